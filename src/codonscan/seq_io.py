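"""Coding-alignment I/O, validation, translation and annotation tables.

Coordinate conventions used throughout the package:

* Nucleotide and amino-acid positions are 1-based inclusive, expressed in the
  coordinate system of the designated *reference* taxon (alignment columns
  where the reference carries a gap are insertions relative to the reference
  and are excluded from reference-coordinate bookkeeping).
* Alignment gaps must occur in codon-sized, codon-aligned runs so that the
  reading frame is preserved in every sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

GAP_CODON = "---"

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "CodingAlignment",
    "TopologyMap",
    "TaxonMetadata",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "translate",
    "read_topology",
    "read_metadata",
]


class AlignmentError(ValueError):
    """Raised when a coding alignment violates frame/stop/length invariants."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table: 61 sense codons plus a set of stop codons."""

    table: dict[str, str]
    stops: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.table) + len(self.stops) != 64:
            raise ValueError(
                f"genetic code must cover 64 codons, got "
                f"{len(self.table)} sense + {len(self.stops)} stops"
            )
        if set(self.table) & set(self.stops):
            raise ValueError("sense and stop codon sets overlap")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.table))

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def aa(self, codon: str) -> str:
        """One-letter amino acid for a sense codon, ``*`` for a stop."""
        if codon in self.stops:
            return "*"
        return self.table[codon]


def _standard_code() -> GeneticCode:
    bt = CodonTable.unambiguous_dna_by_id[1]
    return GeneticCode(table=dict(bt.forward_table), stops=frozenset(bt.stop_codons))


#: The standard nuclear genetic code (NCBI table 1).
STANDARD_CODE = _standard_code()


def translate(
    codon_seq: str,
    code: GeneticCode = STANDARD_CODE,
    *,
    allow_ambiguous: bool = False,
) -> str:
    """Translate an in-frame nucleotide string to one-letter amino acids.

    A gap codon ``---`` translates to ``-``.  A terminal stop codon is
    dropped; an internal stop raises :class:`AlignmentError`.  Codons with
    ambiguous characters raise by default, or translate to ``X`` when
    ``allow_ambiguous`` is set.
    """
    seq = codon_seq.upper()
    if len(seq) % 3:
        raise AlignmentError(f"sequence length {len(seq)} not a multiple of 3")
    n_codons = len(seq) // 3
    out = []
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon == GAP_CODON:
            out.append("-")
            continue
        if "-" in codon:
            raise AlignmentError(f"gap not codon-aligned at codon {i + 1}: {codon!r}")
        if code.is_stop(codon):
            if i == n_codons - 1:
                break  # terminal stop: dropped, not emitted
            raise AlignmentError(f"internal stop codon {codon} at codon {i + 1}")
        aa = code.table.get(codon)
        if aa is None:
            if allow_ambiguous:
                out.append("X")
                continue
            raise AlignmentError(f"ambiguous/invalid codon {codon!r} at codon {i + 1}")
        out.append(aa)
    return "".join(out)


@dataclass
class CodingAlignment:
    """An in-frame codon alignment with a designated reference taxon.

    Sequences are stored uppercase over the alphabet ``ACGT-``; gaps occur
    only as whole, codon-aligned triplets.  A shared terminal stop-codon
    column is stripped on construction so downstream amino-acid bookkeeping
    matches the protein length.
    """

    taxa: list[str]
    sequences: dict[str, str]
    reference: str
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    def __post_init__(self) -> None:
        if not self.taxa:
            raise AlignmentError("alignment has no sequences")
        if self.reference not in self.taxa:
            raise AlignmentError(f"reference taxon {self.reference!r} not in alignment")
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}
        lengths = {len(self.sequences[t]) for t in self.taxa}
        if len(lengths) != 1:
            detail = ", ".join(f"{t}:{len(self.sequences[t])}" for t in self.taxa)
            raise AlignmentError(f"sequences differ in length ({detail})")
        (length,) = lengths
        if length % 3:
            raise AlignmentError(f"alignment length {length} not a multiple of 3")
        self._strip_terminal_stop_column()
        for taxon in self.taxa:
            self._validate_sequence(taxon)

    def _strip_terminal_stop_column(self) -> None:
        length = len(self.sequences[self.taxa[0]])
        if length < 3:
            return
        last = {t: self.sequences[t][length - 3 :] for t in self.taxa}
        ungapped = [c for c in last.values() if c != GAP_CODON]
        if ungapped and all(self.code.is_stop(c) for c in ungapped if "-" not in c):
            if any("-" in c and c != GAP_CODON for c in last.values()):
                return
            self.sequences = {t: s[: length - 3] for t, s in self.sequences.items()}

    def _validate_sequence(self, taxon: str) -> None:
        seq = self.sequences[taxon]
        allowed = set("ACGT-")
        bad = set(seq) - allowed
        if bad:
            raise AlignmentError(f"{taxon}: invalid characters {sorted(bad)}")
        for i in range(len(seq) // 3):
            codon = seq[3 * i : 3 * i + 3]
            if "-" in codon and codon != GAP_CODON:
                raise AlignmentError(
                    f"{taxon}: frame-breaking gap at codon {i + 1} ({codon!r})"
                )
            if codon != GAP_CODON and self.code.is_stop(codon):
                raise AlignmentError(
                    f"{taxon}: internal stop codon {codon} at codon {i + 1}"
                )

    @property
    def length_nt(self) -> int:
        return len(self.sequences[self.taxa[0]])

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    def codon(self, taxon: str, index: int) -> str:
        """Codon at 0-based alignment codon column ``index``."""
        return self.sequences[taxon][3 * index : 3 * index + 3]

    def reference_codon_columns(self) -> list[int]:
        """0-based codon columns where the reference is ungapped, in order.

        Element ``i`` of the returned list is the alignment column of
        reference codon ``i + 1`` (1-based reference coordinates).
        """
        ref = self.sequences[self.reference]
        return [i for i in range(self.n_codons) if ref[3 * i : 3 * i + 3] != GAP_CODON]

    def subset(self, taxa: list[str], reference: str | None = None) -> "CodingAlignment":
        missing = [t for t in taxa if t not in self.sequences]
        if missing:
            raise AlignmentError(f"taxa not in alignment: {missing}")
        ref = reference or (self.reference if self.reference in taxa else taxa[0])
        return CodingAlignment(
            taxa=list(taxa),
            sequences={t: self.sequences[t] for t in taxa},
            reference=ref,
            code=self.code,
        )

    def translated(self, taxon: str) -> str:
        return translate(self.sequences[taxon], self.code)


def read_fasta(
    path: str | Path,
    reference: str | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> CodingAlignment:
    """Read an aligned in-frame FASTA into a validated :class:`CodingAlignment`.

    The taxon label is the header token up to the first whitespace; the
    reference defaults to the first record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise AlignmentError(f"duplicate taxon labels: {dupes}")
    sequences = {r.id: str(r.seq) for r in records}
    return CodingAlignment(
        taxa=taxa,
        sequences=sequences,
        reference=reference or taxa[0],
        code=code,
    )


def write_fasta(aln: CodingAlignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for taxon in aln.taxa:
            fh.write(f">{taxon}\n")
            seq = aln.sequences[taxon]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_REGION_CLASSES = frozenset({"extracellular", "transmembrane", "intracellular"})


@dataclass
class TopologyMap:
    """Receptor domain layout in 1-based inclusive reference AA coordinates."""

    regions: list[tuple[str, int, int]]
    classes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("topology map has no regions")
        expected = 1
        for name, start, end in self.regions:
            if start != expected:
                kind = "overlap" if start < expected else "gap"
                raise ValueError(
                    f"topology {kind} before region {name!r}: "
                    f"expected start {expected}, got {start}"
                )
            if end < start:
                raise ValueError(f"region {name!r} has end {end} < start {start}")
            expected = end + 1
            cls = self.classes.get(name)
            if cls not in _REGION_CLASSES:
                raise ValueError(f"region {name!r}: unknown class {cls!r}")

    @property
    def length(self) -> int:
        return self.regions[-1][2]

    def region_of(self, position: int) -> tuple[str, str]:
        """(region name, class) for a 1-based reference AA position."""
        for name, start, end in self.regions:
            if start <= position <= end:
                return name, self.classes[name]
        raise ValueError(
            f"position {position} outside topology coverage 1..{self.length}"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"region": n, "class": self.classes[n], "start": s, "end": e}
                for n, s, e in self.regions
            ]
        )


def read_topology(path: str | Path, reference_length: int | None = None) -> TopologyMap:
    """Read a TSV with columns region, class, start, end into a TopologyMap."""
    df = pd.read_csv(path, sep="\t")
    required = {"region", "class", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"topology file missing columns: {sorted(missing)}")
    df = df.sort_values("start", kind="stable")
    topo = TopologyMap(
        regions=[(str(r.region), int(r.start), int(r.end)) for r in df.itertuples()],
        classes={str(r.region): str(r["class"]) for _, r in df.iterrows()},
    )
    if reference_length is not None and topo.length != reference_length:
        raise ValueError(
            f"topology covers 1..{topo.length} but reference length is "
            f"{reference_length}"
        )
    return topo


@dataclass
class TaxonMetadata:
    """Per-taxon genus/family/group assignments and the genus-level monogamy flag."""

    rows: dict[str, dict]

    def __post_init__(self) -> None:
        by_genus: dict[str, bool] = {}
        for taxon, row in self.rows.items():
            for key in ("genus", "family", "group", "monogamy"):
                if key not in row:
                    raise ValueError(f"metadata for {taxon!r} missing {key!r}")
            genus = row["genus"]
            flag = bool(row["monogamy"])
            if genus in by_genus and by_genus[genus] != flag:
                raise ValueError(f"monogamy flag inconsistent within genus {genus!r}")
            by_genus[genus] = flag

    def genus(self, taxon: str) -> str:
        return self.rows[taxon]["genus"]

    def family(self, taxon: str) -> str:
        return self.rows[taxon]["family"]

    def group(self, taxon: str) -> str:
        return self.rows[taxon]["group"]

    def monogamous(self, taxon: str) -> bool:
        return bool(self.rows[taxon]["monogamy"])

    def taxa_in_group(self, group: str) -> list[str]:
        return [t for t, r in self.rows.items() if r["group"] == group]

    def genera(self, taxa=None) -> list[str]:
        taxa = self.rows if taxa is None else taxa
        seen: dict[str, None] = {}
        for t in taxa:
            seen.setdefault(self.rows[t]["genus"], None)
        return list(seen)

    def validate_against(self, aln: CodingAlignment) -> None:
        missing = [t for t in aln.taxa if t not in self.rows]
        if missing:
            raise ValueError(f"metadata missing for alignment taxa: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"taxon": t, **row} for t, row in self.rows.items()]
        )


_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}


def read_metadata(path: str | Path) -> TaxonMetadata:
    """Read a TSV with columns taxon, genus, family, group, monogamy."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"taxon", "genus", "family", "group", "monogamy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    rows = {}
    for _, r in df.iterrows():
        raw = str(r["monogamy"]).strip().lower()
        if raw in _TRUTHY:
            flag = True
        elif raw in _FALSY:
            flag = False
        else:
            raise ValueError(f"taxon {r['taxon']!r}: bad monogamy value {r['monogamy']!r}")
        rows[str(r["taxon"])] = {
            "genus": str(r["genus"]),
            "family": str(r["family"]),
            "group": str(r["group"]),
            "monogamy": flag,
        }
    return TaxonMetadata(rows=rows)
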