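"""Substitution calling, physicochemical classification and census statistics.

Amino-acid and nucleotide differences are called against the designated
reference taxon and reported in 1-based reference coordinates.  Replacements
are classified *radical* when they change at least one of charge, polarity or
volume category, *conservative* when they change none — the category tables
ship with documented defaults and are user-replaceable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seq_io import (
    GAP_CODON,
    CodingAlignment,
    GeneticCode,
    TaxonMetadata,
    TopologyMap,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "PhyschemTables",
    "DEFAULT_PHYSCHEM",
    "SubstitutionRecord",
    "DeletionEvent",
    "NtSubstitutionRecord",
    "classify_substitution",
    "call_aa_substitutions",
    "call_nt_substitutions",
    "summarize_by_region",
    "homology_percent",
    "frequency_classes",
    "group_specific_substitutions",
    "read_physchem_tables",
]


def _invert(groups: dict[str, str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for label, members in groups.items():
        for aa in members:
            if aa in out:
                raise ValueError(f"amino acid {aa} assigned twice")
            out[aa] = label
    return out


@dataclass(frozen=True)
class PhyschemTables:
    """Category membership of the 20 amino acids for charge, polarity, volume."""

    charge: dict[str, str]
    polarity: dict[str, str]
    volume: dict[str, str]

    def __post_init__(self) -> None:
        for name in ("charge", "polarity", "volume"):
            table = getattr(self, name)
            covered = set(table)
            if covered != set(AMINO_ACIDS):
                diff = sorted(set(AMINO_ACIDS) ^ covered)
                raise ValueError(f"{name} table must cover all 20 AAs; mismatch {diff}")

    def categories(self, aa: str) -> tuple[str, str, str]:
        return (self.charge[aa], self.polarity[aa], self.volume[aa])


def _default_tables() -> PhyschemTables:
    charge = _invert({"positive": "RKH", "negative": "DE",
                      "neutral": "ACFGILMNPQSTVWY"})
    polarity = _invert({"polar": "RNDCQEGHKSTY", "nonpolar": "AILMFPWV"})
    volume = _invert({"small": "GASCPNDT", "medium": "QEHVM", "large": "RKILFYW"})
    return PhyschemTables(charge=charge, polarity=polarity, volume=volume)


#: Default category tables. Charge: positive {R,K,H}, negative {D,E};
#: polarity: polar {R,N,D,C,Q,E,G,H,K,S,T,Y}; volume: small {G,A,S,C,P,N,D,T},
#: medium {Q,E,H,V,M}, large {R,K,I,L,F,Y,W}.
DEFAULT_PHYSCHEM = _default_tables()


def read_physchem_tables(path: str | Path) -> PhyschemTables:
    """Read a TSV with columns aa, charge, polarity, volume."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"aa", "charge", "polarity", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"physchem table missing columns: {sorted(missing)}")
    return PhyschemTables(
        charge={r.aa: r.charge for r in df.itertuples()},
        polarity={r.aa: r.polarity for r in df.itertuples()},
        volume={r.aa: r.volume for r in df.itertuples()},
    )


def classify_substitution(
    ref_aa: str, alt_aa: str, tables: PhyschemTables = DEFAULT_PHYSCHEM
) -> tuple[str, frozenset[str]]:
    """Classify an AA replacement as radical or conservative.

    Returns ``(classification, categories_changed)`` where classification is
    ``"radical"`` iff the pair differs in at least one of charge, polarity or
    volume.  Symmetric in its two arguments.
    """
    for aa in (ref_aa, alt_aa):
        if aa not in set(AMINO_ACIDS):
            raise ValueError(f"nonstandard amino acid {aa!r}")
    if ref_aa == alt_aa:
        raise ValueError(f"{ref_aa}->{alt_aa} is not a substitution")
    changed = frozenset(
        name
        for name in ("charge", "polarity", "volume")
        if getattr(tables, name)[ref_aa] != getattr(tables, name)[alt_aa]
    )
    return ("radical" if changed else "conservative", changed)


@dataclass
class SubstitutionRecord:
    """One distinct amino-acid replacement observed against the reference."""

    position: int  # 1-based reference AA coordinate
    ref_aa: str
    alt_aa: str
    carriers: frozenset[str]
    domain: str | None = None
    domain_class: str | None = None
    classification: str | None = None
    categories_changed: frozenset[str] = field(default_factory=frozenset)

    def key(self) -> tuple[int, str]:
        return (self.position, self.alt_aa)


@dataclass
class DeletionEvent:
    """A codon-aligned deletion in a non-reference taxon (not a substitution)."""

    start: int  # first deleted reference AA position
    end: int  # last deleted reference AA position (inclusive)
    carriers: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class NtSubstitutionRecord:
    """One distinct nucleotide difference against the reference CDS."""

    nt_position: int  # 1-based reference CDS coordinate
    codon_index: int  # 1-based reference codon (AA) coordinate
    ref_nt: str
    alt_nt: str
    carriers: frozenset[str]
    synonymy: str  # "synonymous" | "nonsynonymous"


def _resolve_subset(aln: CodingAlignment, taxa_subset) -> list[str]:
    if taxa_subset is None:
        return [t for t in aln.taxa if t != aln.reference]
    subset = list(taxa_subset)
    unknown = [t for t in subset if t not in aln.sequences]
    if unknown:
        raise ValueError(f"taxa not in alignment: {unknown}")
    return [t for t in subset if t != aln.reference]


def call_aa_substitutions(
    aln: CodingAlignment,
    code: GeneticCode | None = None,
    topo: TopologyMap | None = None,
    taxa_subset=None,
) -> tuple[list[SubstitutionRecord], list[DeletionEvent]]:
    """Call distinct AA substitutions (and deletion events) vs the reference.

    One record is produced per distinct ``(reference position, alt AA)`` pair
    observed in at least one subset taxon; taxa sharing the same replacement
    are merged into the record's carrier set.  Codon-aligned gap runs in
    non-reference taxa become :class:`DeletionEvent`s, never substitutions.
    Alignment columns where the reference is gapped (insertions) are excluded.
    """
    code = code or aln.code
    subset = _resolve_subset(aln, taxa_subset)
    ref_cols = aln.reference_codon_columns()
    if topo is not None and len(ref_cols) != topo.length:
        raise ValueError(
            f"reference protein length {len(ref_cols)} does not match "
            f"topology coverage 1..{topo.length}"
        )

    by_key: dict[tuple[int, str], set[str]] = {}
    ref_aas: dict[int, str] = {}
    del_runs: dict[tuple[int, int], set[str]] = {}
    open_runs: dict[str, int | None] = {t: None for t in subset}

    for pos, col in enumerate(ref_cols, start=1):
        ref_codon = aln.codon(aln.reference, col)
        ref_aa = code.aa(ref_codon)
        ref_aas[pos] = ref_aa
        for taxon in subset:
            codon = aln.codon(taxon, col)
            if codon == GAP_CODON:
                if open_runs[taxon] is None:
                    open_runs[taxon] = pos
                continue
            if open_runs[taxon] is not None:
                run = (open_runs[taxon], pos - 1)
                del_runs.setdefault(run, set()).add(taxon)
                open_runs[taxon] = None
            aa = code.aa(codon)
            if aa != ref_aa:
                by_key.setdefault((pos, aa), set()).add(taxon)
    last_pos = len(ref_cols)
    for taxon, start in open_runs.items():
        if start is not None:
            del_runs.setdefault((start, last_pos), set()).add(taxon)

    records = []
    for (pos, alt_aa), carriers in sorted(by_key.items()):
        ref_aa = ref_aas[pos]
        domain = domain_class = None
        if topo is not None:
            domain, domain_class = topo.region_of(pos)
        classification, changed = classify_substitution(ref_aa, alt_aa)
        records.append(
            SubstitutionRecord(
                position=pos,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                carriers=frozenset(carriers),
                domain=domain,
                domain_class=domain_class,
                classification=classification,
                categories_changed=changed,
            )
        )
    deletions = [
        DeletionEvent(start=s, end=e, carriers=frozenset(c))
        for (s, e), c in sorted(del_runs.items())
    ]
    return records, deletions


def call_nt_substitutions(
    aln: CodingAlignment,
    code: GeneticCode | None = None,
    taxa_subset=None,
) -> list[NtSubstitutionRecord]:
    """Call distinct nucleotide substitutions vs the reference CDS.

    Synonymy of each variant is judged with the other two codon positions
    held at the reference state, i.e. as a single substitution in the
    reference codon context.  Codons where the observed taxon codon differs
    from the reference at more than one position are still decomposed into
    their single-base variants (each judged in reference context) and a
    multi-hit warning is logged.
    """
    code = code or aln.code
    subset = _resolve_subset(aln, taxa_subset)
    ref_cols = aln.reference_codon_columns()
    by_key: dict[tuple[int, str], set[str]] = {}
    ref_nts: dict[int, str] = {}
    synonymy_of: dict[tuple[int, str], str] = {}

    for pos, col in enumerate(ref_cols, start=1):
        ref_codon = aln.codon(aln.reference, col)
        for taxon in subset:
            codon = aln.codon(taxon, col)
            if codon == GAP_CODON:
                continue  # gap column: record suppressed for gapped taxa
            diffs = [k for k in range(3) if codon[k] != ref_codon[k]]
            if len(diffs) > 1:
                logger.warning(
                    "multi-hit codon at reference codon %d (%s: %s vs %s); "
                    "variants judged in reference context",
                    pos, taxon, codon, ref_codon,
                )
            for k in diffs:
                nt_position = 3 * (pos - 1) + k + 1
                key = (nt_position, codon[k])
                by_key.setdefault(key, set()).add(taxon)
                ref_nts[nt_position] = ref_codon[k]
                if key not in synonymy_of:
                    mutant = ref_codon[:k] + codon[k] + ref_codon[k + 1 :]
                    same = code.aa(mutant) == code.aa(ref_codon)
                    synonymy_of[key] = "synonymous" if same else "nonsynonymous"

    return [
        NtSubstitutionRecord(
            nt_position=nt_pos,
            codon_index=(nt_pos - 1) // 3 + 1,
            ref_nt=ref_nts[nt_pos],
            alt_nt=alt,
            carriers=frozenset(carriers),
            synonymy=synonymy_of[(nt_pos, alt)],
        )
        for (nt_pos, alt), carriers in sorted(by_key.items())
    ]


def summarize_by_region(
    records: list[SubstitutionRecord], topo: TopologyMap
) -> pd.DataFrame:
    """Per-region substitution census.

    ``fraction`` is distinct substituted positions over region length; radical
    and conservative counts are per record, so a position with two alt states
    can contribute two records.
    """
    rows = []
    for name, start, end in topo.regions:
        in_region = [r for r in records if start <= r.position <= end]
        positions = {r.position for r in in_region}
        length = end - start + 1
        rows.append(
            {
                "region": name,
                "class": topo.classes[name],
                "region_length": length,
                "n_substituted_positions": len(positions),
                "fraction": len(positions) / length,
                "n_records": len(in_region),
                "n_radical": sum(r.classification == "radical" for r in in_region),
                "n_conservative": sum(
                    r.classification == "conservative" for r in in_region
                ),
            }
        )
    return pd.DataFrame(rows)


def homology_percent(
    aln: CodingAlignment,
    taxon: str,
    reference: str | None = None,
    code: GeneticCode | None = None,
) -> float:
    """Percent AA identity of ``taxon`` with the reference protein.

    The denominator is the reference protein length; positions deleted in the
    query count as mismatches.
    """
    code = code or aln.code
    reference = reference or aln.reference
    ref_cols = aln.reference_codon_columns()
    identical = 0
    for col in ref_cols:
        ref_codon = aln.codon(reference, col)
        codon = aln.codon(taxon, col)
        if codon == GAP_CODON or ref_codon == GAP_CODON:
            continue
        if code.aa(codon) == code.aa(ref_codon):
            identical += 1
    return 100.0 * identical / len(ref_cols)


def frequency_classes(
    records: list[SubstitutionRecord],
    metadata: TaxonMetadata,
    target_taxa: list[str],
    threshold: float = 0.94,
) -> pd.DataFrame:
    """Classify each substitution by its genus-level carrier frequency.

    Frequency is the fraction of target genera with at least one carrier.
    Classes: ``conserved`` (all genera), ``high-frequency`` (> threshold),
    ``genus-specific`` (exactly one genus), else ``intermediate``.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    target = set(target_taxa)
    genera = metadata.genera(target_taxa)
    n_genera = len(genera)
    rows = []
    for rec in records:
        carrier_genera = {
            metadata.genus(t) for t in rec.carriers if t in target
        }
        freq = len(carrier_genera) / n_genera
        if freq == 1.0:
            cls = "conserved"
        elif freq > threshold:
            cls = "high-frequency"
        elif len(carrier_genera) == 1:
            cls = "genus-specific"
        else:
            cls = "intermediate"
        rows.append(
            {
                "position": rec.position,
                "ref_aa": rec.ref_aa,
                "alt_aa": rec.alt_aa,
                "n_carrier_genera": len(carrier_genera),
                "n_genera": n_genera,
                "frequency": freq,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


def group_specific_substitutions(
    records: list[SubstitutionRecord],
    in_group: list[str],
    out_group: list[str],
) -> list[SubstitutionRecord]:
    """Substitutions carried by every in-group taxon and no out-group taxon."""
    in_set, out_set = set(in_group), set(out_group)
    if not in_set:
        raise ValueError("in-group is empty")
    return [
        r
        for r in records
        if in_set <= r.carriers and not (out_set & r.carriers)
    ]


def records_to_frame(records: list[SubstitutionRecord]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of substitution records."""
    return pd.DataFrame(
        [
            {
                "position": r.position,
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "domain": r.domain,
                "domain_class": r.domain_class,
                "classification": r.classification,
                "categories_changed": ",".join(sorted(r.categories_changed)),
                "n_carriers": len(r.carriers),
                "carriers": ",".join(sorted(r.carriers)),
            }
            for r in records
        ]
    )
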