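"""End-to-end orchestration: substitution census → dN/dS scan → phylogeny →
site-model selection tests → report, from one YAML-able config.

Every stage writes its TSV next to a MANIFEST.json recording the parameters
actually used, so a run is self-describing and byte-reproducible under a
fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import dnds, phylo, possel, substitutions
from .seq_io import (
    CodingAlignment,
    TaxonMetadata,
    TopologyMap,
    read_fasta,
    read_metadata,
    read_topology,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    alignment: str
    out_dir: str
    seed: int
    reference: str | None = None
    topology: str | None = None
    metadata: str | None = None
    tree: str | None = None  # optional externally supplied newick
    outgroup: str | None = None
    analysis_group: str | None = None  # metadata 'group' naming the study taxa
    clade_taxa: list[str] = field(default_factory=list)  # in-group for
    # clade-specific substitution detection; default: monogamous taxa
    window_len: int = 50
    window_step: int = 10
    window_units: str = "codon"
    gamma_shape: float = 1.0
    bootstrap_reps: int = 200
    frequency_threshold: float = 0.94
    possel_models: list[str] = field(default_factory=lambda: ["m0", "m8", "m8a"])
    possel_classes: int = 10
    possel_freq: str = "f3x4"
    possel_restarts: int = 2
    possel_maxiter: int = 300
    possel_taxa: list[str] | None = None  # optional subset to bound runtime

    def validate(self) -> None:
        for label, path in (
            ("alignment", self.alignment),
            ("topology", self.topology),
            ("metadata", self.metadata),
            ("tree", self.tree),
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = set(self.possel_models) - {"m0", "m8", "m8a"}
        if unknown:
            raise ValueError(f"unknown site models: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_pipeline(
    config: RunConfig,
    aln: CodingAlignment | None = None,
    topo: TopologyMap | None = None,
    metadata: TaxonMetadata | None = None,
) -> dict:
    """Run every configured stage; returns a summary dict (also in report.md).

    Pre-loaded objects may be passed directly (the in-memory entry point the
    simulator fixtures use); otherwise they are read from the config paths.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "config": asdict(config)}
    summary: dict = {}

    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("codonscan")
    root.addHandler(log_handler)
    try:
        aln = aln or read_fasta(config.alignment, reference=config.reference)
        if topo is None and config.topology:
            topo = read_topology(config.topology)
        if metadata is None and config.metadata:
            metadata = read_metadata(config.metadata)
        if metadata is not None:
            metadata.validate_against(aln)

        study_taxa = [t for t in aln.taxa if t != aln.reference]
        if metadata is not None and config.analysis_group:
            study_taxa = [
                t for t in metadata.taxa_in_group(config.analysis_group)
                if t in aln.sequences
            ]

        # --- substitution census ---------------------------------------
        records, deletions = substitutions.call_aa_substitutions(
            aln, topo=topo, taxa_subset=study_taxa
        )
        nt_records = substitutions.call_nt_substitutions(aln, taxa_subset=study_taxa)
        _write_tsv(substitutions.records_to_frame(records), out / "substitutions.tsv")
        nt_df = pd.DataFrame(
            [
                {
                    "nt_position": r.nt_position,
                    "codon_index": r.codon_index,
                    "ref_nt": r.ref_nt,
                    "alt_nt": r.alt_nt,
                    "synonymy": r.synonymy,
                    "n_carriers": len(r.carriers),
                    "carriers": ",".join(sorted(r.carriers)),
                }
                for r in nt_records
            ]
        )
        _write_tsv(nt_df, out / "nt_substitutions.tsv")
        summary["n_aa_substitutions"] = len(records)
        summary["n_nt_substitutions"] = len(nt_records)
        summary["n_radical"] = sum(r.classification == "radical" for r in records)
        summary["n_conservative"] = sum(
            r.classification == "conservative" for r in records
        )
        summary["n_deletion_events"] = len(deletions)
        manifest["stages"].append("substitutions")

        if topo is not None:
            region_df = substitutions.summarize_by_region(records, topo)
            _write_tsv(region_df, out / "regions.tsv")
            manifest["stages"].append("regions")
        else:
            region_df = None

        homology_df = pd.DataFrame(
            [
                {
                    "taxon": t,
                    "homology_percent": substitutions.homology_percent(aln, t),
                }
                for t in study_taxa
            ]
        )
        _write_tsv(homology_df, out / "homology.tsv")
        manifest["stages"].append("homology")

        clade_records: list = []
        if metadata is not None:
            freq_df = substitutions.frequency_classes(
                records, metadata, study_taxa, threshold=config.frequency_threshold
            )
            _write_tsv(freq_df, out / "frequency_classes.tsv")
            summary["n_conserved"] = int((freq_df["class"] == "conserved").sum())
            manifest["stages"].append("frequency_classes")

            in_group = config.clade_taxa or [
                t for t in study_taxa if metadata.monogamous(t)
            ]
            if in_group:
                out_group = [t for t in study_taxa if t not in set(in_group)]
                clade_records = substitutions.group_specific_substitutions(
                    records, in_group, out_group
                )
                _write_tsv(
                    substitutions.records_to_frame(clade_records),
                    out / "clade_specific.tsv",
                )
                summary["n_clade_specific"] = len(clade_records)
                manifest["stages"].append("clade_specific")

        # --- dN/dS -------------------------------------------------------
        overall = dnds.mean_dnds(aln, taxa_subset=study_taxa + [aln.reference])
        summary["mean_dnds"] = overall.ratio
        pairs = [(t, aln.reference) for t in study_taxa]
        profile = dnds.sliding_window_dnds(
            aln,
            pairs=pairs,
            window_len=config.window_len,
            step=config.window_step,
            units=config.window_units,
        )
        win_df = pd.DataFrame(
            profile.windows, columns=["midpoint", "dN", "dS", "ratio"]
        )
        _write_tsv(win_df, out / "windows.tsv")
        manifest["stages"].append("dnds")

        # --- phylogeny ---------------------------------------------------
        if config.tree:
            tree = phylo.from_newick(Path(config.tree).read_text())
        else:
            tree = phylo.bootstrap_support(
                aln,
                n_reps=config.bootstrap_reps,
                seed=config.seed,
                gamma_shape=config.gamma_shape,
            )
        if config.outgroup:
            tree = phylo.root_with_outgroup(tree, config.outgroup)
        (out / "tree.nwk").write_text(tree.to_newick())
        manifest["stages"].append("phylo")

        # --- site models ---------------------------------------------------
        fits: dict[str, possel.SiteModelFit] = {}
        if config.possel_models:
            possel_taxa = config.possel_taxa or list(aln.taxa)
            sub = aln.subset(possel_taxa, reference=aln.reference
                             if aln.reference in possel_taxa else None)
            fit0 = possel.fit_m0(
                sub, seed=config.seed, restarts=config.possel_restarts,
                maxiter=config.possel_maxiter, freq=config.possel_freq,
            )
            if "m0" in config.possel_models:
                fits["m0"] = fit0
                summary["m0_omega"] = float(fit0.params.omega_classes[0])
                summary["m0_kappa"] = float(fit0.params.kappa)
            if "m8a" in config.possel_models or "m8" in config.possel_models:
                fit8a = possel.fit_m8a(
                    sub, fit0.tree, k_classes=config.possel_classes,
                    seed=config.seed, restarts=config.possel_restarts,
                    maxiter=config.possel_maxiter, freq=config.possel_freq,
                )
                fits["m8a"] = fit8a
                if "m8" in config.possel_models:
                    fit8 = possel.fit_m8(
                        sub, fit0.tree, k_classes=config.possel_classes,
                        seed=config.seed, restarts=config.possel_restarts,
                        maxiter=config.possel_maxiter, freq=config.possel_freq,
                        m8a_fit=fit8a,
                    )
                    fits["m8"] = fit8
                    stat, pval = possel.lrt_m8_m8a(fit8, fit8a)
                    summary["lrt_statistic"] = stat
                    summary["lrt_p_value"] = pval
                    sites = possel.neb_sites(fit8)
                    sites_df = pd.DataFrame(
                        sites, columns=["position", "posterior"]
                    )
                    _write_tsv(sites_df, out / "sites.tsv")
                    summary["n_selected_sites"] = len(sites)
            fit_json = {
                name: {
                    "model": fit.model,
                    "lnL": fit.lnL,
                    "kappa": fit.params.kappa,
                    "omega_classes": [float(w) for w in fit.params.omega_classes],
                    "class_weights": [float(w) for w in fit.params.class_weights],
                    "extra": {
                        k: v for k, v in fit.params.extra.items()
                        if not k.startswith("_")
                    },
                }
                for name, fit in fits.items()
            }
            (out / "fit.json").write_text(json.dumps(fit_json, indent=2, sort_keys=True))
            manifest["stages"].append("possel")

        _write_report(out, summary, records, region_df, clade_records, win_df)
        manifest["summary"] = _jsonable(summary)
        (out / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
    return summary


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        try:
            json.dumps(v)
            out[k] = v
        except TypeError:
            out[k] = str(v)
    return out


def _write_report(out, summary, records, region_df, clade_records, win_df) -> None:
    lines = ["# Pipeline report", ""]
    lines.append(
        f"{summary['n_aa_substitutions']} AA substitutions "
        f"({summary['n_radical']} radical / {summary['n_conservative']} "
        f"conservative) from {summary['n_nt_substitutions']} nucleotide "
        f"substitutions; {summary['n_deletion_events']} deletion events."
    )
    # internal consistency check: report counts equal stage-table sums
    assert summary["n_radical"] + summary["n_conservative"] == len(records)
    if region_df is not None:
        lines.append("")
        lines.append("Per-region substituted positions:")
        for _, row in region_df.iterrows():
            lines.append(
                f"- {row.region} ({row['class']}): "
                f"{row.n_substituted_positions}/{row.region_length} "
                f"({100 * row.fraction:.1f}%), {row.n_radical} radical / "
                f"{row.n_conservative} conservative"
            )
        assert int(region_df["n_records"].sum()) == len(records)
    if clade_records:
        positions = ", ".join(str(r.position) for r in clade_records)
        lines.append("")
        lines.append(
            f"{len(clade_records)} clade-specific substitutions at positions "
            f"{positions}."
        )
    ratio = summary.get("mean_dnds")
    if ratio is not None:
        lines.append("")
        lines.append(f"Overall dN/dS (pooled NG86): {ratio:.3f}")
    valid = win_df.dropna(subset=["ratio"])
    if len(valid):
        peak = valid.loc[valid["ratio"].idxmax()]
        lines.append(
            f"Sliding-window peak dN/dS {peak.ratio:.2f} at codon midpoint "
            f"{peak.midpoint:.0f}."
        )
    if "m0_omega" in summary:
        lines.append("")
        lines.append(
            f"M0 fit: omega = {summary['m0_omega']:.3f}, "
            f"kappa = {summary['m0_kappa']:.2f}."
        )
    if "lrt_statistic" in summary:
        lines.append(
            f"M8 vs M8a LRT: statistic = {summary['lrt_statistic']:.2f}, "
            f"p = {summary['lrt_p_value']:.4g}; "
            f"{summary['n_selected_sites']} sites with NEB posterior > 0.95."
        )
    Path(out, "report.md").write_text("\n".join(lines) + "\n")
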