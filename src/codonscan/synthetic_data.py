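"""Codon-alignment simulator with known ground truth.

Sequences evolve on a known tree under the GY94 model: root codons are drawn
from the equilibrium frequencies and each branch applies the exact transition
matrix P(t) = exp(Qt) for the site's ω class — no intermediate-event
simulation, so the generating process matches the likelihood model exactly.

The headline fixture, :func:`make_receptor_fixture`, emulates a GPCR-style
dataset: a reference taxon plus three ingroup families and a divergent
outgroup, purifying selection genome-wide (ω ≈ 0.1) but elevated ω in three
designated receptor regions, and four clade-specific substitutions planted
in a designated "monogamous" subclade — the structure every downstream stage
(substitution census, sliding window, phylogeny, site models) is meant to
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import possel
from .phylo import TreeNode, from_newick
from .seq_io import (
    CodingAlignment,
    GeneticCode,
    STANDARD_CODE,
    TaxonMetadata,
    TopologyMap,
)

__all__ = [
    "SimulationSpec",
    "TruthRecord",
    "simulate_alignment",
    "make_receptor_fixture",
    "ReceptorFixture",
]


@dataclass
class SimulationSpec:
    """Everything needed to simulate one codon alignment reproducibly."""

    tree: str  # newick with branch lengths (expected substitutions/codon)
    n_codons: int
    seed: int
    kappa: float = 2.0
    pi: np.ndarray | None = None  # default: uniform over sense codons
    site_omega_map: list[tuple[int, int, float]] = field(default_factory=list)
    default_omega: float = 0.1
    reference_taxon: str | None = None
    planted_substitutions: list[tuple[tuple[str, ...], int, str]] = field(
        default_factory=list
    )  # (clade taxa, 1-based codon position, forced alt codon)
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    def site_omegas(self) -> np.ndarray:
        omegas = np.full(self.n_codons, self.default_omega, dtype=float)
        covered = np.zeros(self.n_codons, dtype=bool)
        for start, end, omega in self.site_omega_map:
            if not (1 <= start <= end <= self.n_codons):
                raise ValueError(
                    f"omega interval ({start}, {end}) outside 1..{self.n_codons}"
                )
            idx = slice(start - 1, end)
            if covered[idx].any():
                raise ValueError(f"omega intervals overlap at ({start}, {end})")
            covered[idx] = True
            omegas[idx] = omega
        return omegas


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated alignment."""

    tree: str
    site_omegas: np.ndarray
    planted: list[tuple[tuple[str, ...], int, str]]
    spec: SimulationSpec

    def to_dict(self) -> dict:
        return {
            "tree": self.tree,
            "site_omegas": [float(w) for w in self.site_omegas],
            "planted": [
                {"clade": list(clade), "position": pos, "alt_codon": codon}
                for clade, pos, codon in self.planted
            ],
            "kappa": self.spec.kappa,
            "seed": self.spec.seed,
        }


def _branch_streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """One named child RNG stream per branch, so draws do not depend on the
    order in which branches are visited."""
    order = sorted(names)
    seqs = np.random.SeedSequence(seed).spawn(len(order))
    return {name: np.random.default_rng(s) for name, s in zip(order, seqs)}


def simulate_alignment(spec: SimulationSpec) -> tuple[CodingAlignment, TruthRecord]:
    """Simulate a gap-free codon alignment under the spec's GY94 regime."""
    code = spec.code
    codons = code.sense_codons
    n_states = len(codons)
    pi = (
        np.full(n_states, 1.0 / n_states)
        if spec.pi is None
        else np.asarray(spec.pi, float)
    )
    tree = from_newick(spec.tree)
    leaves = tree.leaf_names()
    if len(set(leaves)) != len(leaves):
        raise ValueError("tree has duplicate leaf labels")

    omegas = spec.site_omegas()
    unique_omegas = sorted(set(float(w) for w in omegas))
    sites_of = {w: np.nonzero(omegas == w)[0] for w in unique_omegas}

    # Mixture-consistent scaling: one scale factor over the site-ω profile.
    params = possel.CodonModelParams(
        kappa=spec.kappa,
        omega_classes=np.array(unique_omegas),
        class_weights=np.array(
            [len(sites_of[w]) / spec.n_codons for w in unique_omegas]
        ),
        pi=pi,
        code=code,
    )
    qs = possel._mixture_rate_matrices(params)
    decomps = {
        w: possel._eigendecompose(q, pi) for w, q in zip(unique_omegas, qs)
    }

    # Name internal branches deterministically by their smallest leaf + depth
    # so every branch gets a stable RNG stream name.
    branch_names: dict[int, str] = {}
    counter: dict[str, int] = {}
    for node in tree.postorder():
        if node is tree:
            continue
        label = min(n.name for n in node.leaves())
        k = counter.get(label, 0)
        counter[label] = k + 1
        branch_names[id(node)] = f"{label}#{k}"
    streams = _branch_streams(spec.seed, ["__root__"] + list(branch_names.values()))

    states: dict[int, np.ndarray] = {}
    root_rng = streams["__root__"]
    states[id(tree)] = root_rng.choice(n_states, size=spec.n_codons, p=pi)

    def preorder(node: TreeNode):
        yield node
        for child in node.children:
            yield from preorder(child)

    for node in preorder(tree):
        for child in node.children:
            rng = streams[branch_names[id(child)]]
            parent_states = states[id(node)]
            child_states = np.empty(spec.n_codons, dtype=int)
            t = max(child.length, 0.0)
            for w in unique_omegas:
                idx = sites_of[w]
                if len(idx) == 0:
                    continue
                P = possel._probs_from_decomposition(decomps[w], t)
                cum = np.cumsum(P, axis=1)
                u = rng.random(len(idx))
                rows = cum[parent_states[idx]]
                child_states[idx] = (u[:, None] < rows).argmax(axis=1)
            states[id(child)] = child_states

    sequences = {
        leaf.name: "".join(codons[s] for s in states[id(leaf)])
        for leaf in tree.leaves()
    }

    reference = spec.reference_taxon or sorted(sequences)[0]
    for clade, position, alt_codon in spec.planted_substitutions:
        if not (1 <= position <= spec.n_codons):
            raise ValueError(f"planted position {position} outside alignment")
        alt_codon = alt_codon.upper()
        if alt_codon not in code.table:
            raise ValueError(f"planted codon {alt_codon!r} is not a sense codon")
        ref_codon = sequences[reference][3 * (position - 1) : 3 * position]
        if code.table[alt_codon] == code.aa(ref_codon):
            raise ValueError(
                f"planted codon {alt_codon} is synonymous with the reference "
                f"at position {position}"
            )
        for taxon in sequences:
            if taxon == reference:
                continue
            codon = alt_codon if taxon in clade else ref_codon
            seq = sequences[taxon]
            sequences[taxon] = seq[: 3 * (position - 1)] + codon + seq[3 * position :]

    aln = CodingAlignment(
        taxa=sorted(sequences),
        sequences=sequences,
        reference=reference,
        code=code,
    )
    truth = TruthRecord(
        tree=spec.tree,
        site_omegas=omegas,
        planted=list(spec.planted_substitutions),
        spec=spec,
    )
    return aln, truth


@dataclass
class ReceptorFixture:
    """A simulated receptor-style dataset bundle with its ground truth."""

    alignment: CodingAlignment
    topology: TopologyMap
    metadata: TaxonMetadata
    truth: TruthRecord

    @property
    def elevated_regions(self) -> list[tuple[int, int]]:
        return [
            (start, end)
            for start, end, omega in self.truth.spec.site_omega_map
            if omega >= 1.0
        ]


def _scrub_accidental_clade_records(aln: CodingAlignment, planted_positions) -> None:
    """Keep the planted substitutions the *only* clade-wide ones.

    Parallel substitutions on the two pair-stems inside the monogamous
    subclade occasionally produce a record carried by exactly those four
    taxa.  Reverting one clade member to the reference codon at any such
    non-planted position breaks the accidental sharing without touching the
    planted truth.
    """
    from .substitutions import call_aa_substitutions, group_specific_substitutions

    ingroup = [t for t in aln.taxa if t not in ("Reference", "Outgroup")]
    in_clade = list(FIXTURE_MONOGAMOUS_CLADE)
    out_clade = [t for t in ingroup if t not in FIXTURE_MONOGAMOUS_CLADE]
    records, _ = call_aa_substitutions(aln, taxa_subset=ingroup)
    accidental = [
        r
        for r in group_specific_substitutions(records, in_clade, out_clade)
        if r.position not in planted_positions
    ]
    fixer = in_clade[-1]
    for rec in accidental:
        i = rec.position - 1  # fixture reference is gap-free
        ref_codon = aln.sequences[aln.reference][3 * i : 3 * i + 3]
        seq = aln.sequences[fixer]
        aln.sequences[fixer] = seq[: 3 * i] + ref_codon + seq[3 * i + 3 :]


# Receptor-style domain layout (1-based AA coordinates, 420 residues):
# an extracellular N-terminus, seven TM helices with connecting loops, and
# an intracellular C-terminus. Elevated ω is planted in Nterm, IC3 and Cterm.
_FIXTURE_REGIONS = [
    ("Nterm", 1, 52, "extracellular"),
    ("TM1", 53, 75, "transmembrane"),
    ("IC1", 76, 85, "intracellular"),
    ("TM2", 86, 110, "transmembrane"),
    ("EC2", 111, 125, "extracellular"),
    ("TM3", 126, 150, "transmembrane"),
    ("IC2", 151, 165, "intracellular"),
    ("TM4", 166, 190, "transmembrane"),
    ("EC3", 191, 209, "extracellular"),
    ("TM5", 210, 234, "transmembrane"),
    ("IC3", 235, 288, "intracellular"),
    ("TM6", 289, 313, "transmembrane"),
    ("EC4", 314, 327, "extracellular"),
    ("TM7", 328, 353, "transmembrane"),
    ("Cterm", 354, 420, "intracellular"),
]

#: Taxa of the "monogamous" ingroup subclade carrying planted substitutions.
FIXTURE_MONOGAMOUS_CLADE = ("GenA1", "GenA2", "GenA3", "GenA4")

#: Planted clade-specific positions with a preference-ordered chain of alt
#: codons; the first one non-synonymous with the simulated reference codon is
#: used, so the plant is valid whatever the seed produced at that position.
_FIXTURE_PLANTS = [241, 319, 399, 409]
_FIXTURE_ALT_CHAIN = ["TGT", "AAT", "GTT", "CGT", "GAA", "TGG"]


def _fixture_tree(depth: float) -> str:
    """Three six-taxon ingroup families, a reference lineage, and an outgroup."""

    def clade(names: list[str], tip: float, inner: float, stem4: float | None = None) -> str:
        # ladderized pairs of pairs: ((a,b),(c,d),(e,f)) with stem lengths
        a, b, c, d, e, f = names
        s4 = inner if stem4 is None else stem4
        return (
            f"((({a}:{tip},{b}:{tip}):{inner},({c}:{tip},{d}:{tip}):{inner})"
            f":{s4},({e}:{tip},{f}:{tip}):{inner})"
        )

    tip = 0.3 * depth
    inner = 0.25 * depth
    stem = 0.5 * depth
    # The (GenA1..GenA4) subclade carries the planted clade-specific
    # substitutions; its stem is zero-length so no *natural* substitution can
    # be shared by exactly those four taxa — the planted records are the only
    # clade-wide ones, which is what downstream truth checks rely on.
    fam_a = clade(["GenA1", "GenA2", "GenA3", "GenA4", "GenA5", "GenA6"],
                  tip, inner, stem4=0.0)
    fam_b = clade(["GenB1", "GenB2", "GenB3", "GenB4", "GenB5", "GenB6"], tip, inner)
    fam_c = clade(["GenC1", "GenC2", "GenC3", "GenC4", "GenC5", "GenC6"], tip, inner)
    ingroup = f"(({fam_a}:{stem},{fam_b}:{stem}):{inner},{fam_c}:{stem})"
    return (
        f"(({ingroup}:{stem},Reference:{1.2 * depth}):{stem},"
        f"Outgroup:{2.5 * depth});"
    )


def make_receptor_fixture(
    seed: int,
    n_codons: int = 420,
    depth: float = 0.25,
    elevated_omega: float = 2.0,
    baseline_omega: float = 0.1,
) -> ReceptorFixture:
    """Simulate the receptor-style study bundle.

    Twenty taxa (18 ingroup across three families, one reference lineage,
    one divergent outgroup) over 420 codons; ω is ``baseline_omega`` except
    in the N-terminus, third intracellular loop and C-terminus where it is
    ``elevated_omega``; four clade-specific substitutions are planted in the
    monogamous subclade (GenA1–GenA4).
    """
    regions = [(n, s, e) for n, s, e, _ in _FIXTURE_REGIONS]
    classes = {n: c for n, s, e, c in _FIXTURE_REGIONS}
    if n_codons != regions[-1][2]:
        raise ValueError(f"n_codons must be {regions[-1][2]} to match the layout")
    omega_map = [
        (s, e, elevated_omega)
        for (name, s, e) in regions
        if name in {"Nterm", "IC3", "Cterm"}
    ]
    base_kwargs = dict(
        tree=_fixture_tree(depth),
        n_codons=n_codons,
        seed=seed,
        kappa=2.5,
        site_omega_map=omega_map,
        default_omega=baseline_omega,
        reference_taxon="Reference",
    )
    # Dry run (plants are applied post hoc, so RNG draws are identical):
    # learn the reference codons at the planted positions, then pick each
    # alt codon as the first chain entry that is non-synonymous with them.
    dry_aln, _ = simulate_alignment(SimulationSpec(**base_kwargs))
    code = dry_aln.code
    plants = []
    for pos in _FIXTURE_PLANTS:
        ref_codon = dry_aln.sequences["Reference"][3 * (pos - 1) : 3 * pos]
        alt = next(
            c for c in _FIXTURE_ALT_CHAIN if code.table[c] != code.aa(ref_codon)
        )
        plants.append((FIXTURE_MONOGAMOUS_CLADE, pos, alt))
    spec = SimulationSpec(**base_kwargs, planted_substitutions=plants)
    aln, truth = simulate_alignment(spec)
    _scrub_accidental_clade_records(aln, set(_FIXTURE_PLANTS))
    topo = TopologyMap(regions=regions, classes=classes)
    rows = {}
    for taxon in aln.taxa:
        if taxon == "Reference":
            rows[taxon] = {"genus": "RefGenus", "family": "RefFamily",
                           "group": "reference", "monogamy": False}
        elif taxon == "Outgroup":
            rows[taxon] = {"genus": "OutGenus", "family": "OutFamily",
                           "group": "outgroup", "monogamy": False}
        else:
            family = {"A": "FamilyA", "B": "FamilyB", "C": "FamilyC"}[taxon[3]]
            rows[taxon] = {
                "genus": f"Genus{taxon[3:]}",
                "family": family,
                "group": "ingroup",
                "monogamy": taxon in FIXTURE_MONOGAMOUS_CLADE,
            }
    metadata = TaxonMetadata(rows=rows)
    return ReceptorFixture(alignment=aln, topology=topo, metadata=metadata, truth=truth)
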