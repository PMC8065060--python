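"""Pipeline orchestration: cohort in, publication-style result bundle out.

The bundle mirrors the analysis sequence: a motif-level allelic table, a
genotype-level one-vs-rest table, the genotype-group pairing table for risk
motifs, the DR-DQ joint haplotype table, per-antibody motif associations, the
attributable-fraction table, group entropies, and the motif cluster tree in
Newick form.  Every filtering step (rare exclusions, minimum-copy rules) is
recorded in the run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import DistanceMatrix, cluster, to_newick
from .motifs import (CASE, CONTROL, attach_motifs, classify_motif,
                     collapse_rare, motif_copy_counts, phase_em,
                     pool_rare_genotypes)
from .registry import ResiduePanel, load_default_registry, load_registry
from .stats import (autoantibody_panel, drdq_haplotype_analysis,
                    genotype_group_analysis, one_vs_rest_test,
                    virtual_reference_or)
from .summaries import af_pipeline, group_entropies

log = logging.getLogger("dqmotif")


@dataclass
class PipelineConfig:
    registry_path: str | None = None      # None -> packaged fixture
    cohort_path: str | None = None
    output_dir: str | None = None
    phased: bool = True                   # False -> run EM phasing
    rare_threshold: int = 5               # motif-level exclusion (copies)
    genotype_rare_threshold: int = 5      # genotype pooling (subjects)
    antibody_min_copies: int = 10
    alpha: float = 0.05
    posterior_threshold: float = 0.97
    entropy_base: float = math.e
    or_convention: str = "or_virtual"
    cluster_k: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        for t in (self.rare_threshold, self.genotype_rare_threshold,
                  self.antibody_min_copies):
            if t < 1:
                raise ValueError("thresholds must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a YAML or JSON config (YAML is a JSON superset, so one parser
        serves both)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**(data or {}))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    motif_table: pd.DataFrame
    genotype_table: pd.DataFrame
    genotype_group_table: pd.DataFrame | None
    drdq_table: pd.DataFrame | None
    antibody_table: pd.DataFrame | None
    af_table: pd.DataFrame | None
    entropy: dict
    newick: str
    classes: dict
    run_log: list = field(default_factory=list)


def load_cohort(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def motif_association_table(cohort_m: pd.DataFrame, rare_threshold: int = 5,
                            alpha: float = 0.05, run_log: list | None = None
                            ) -> tuple[pd.DataFrame, dict]:
    """Allelic (motif-copy) association table with rare motifs excluded.

    Returns the table plus the motif->class assignment (rare motifs classed
    'rare'; retained motifs classed by OR direction and significance).
    """
    counts = motif_copy_counts(cohort_m)
    res = collapse_rare(counts, threshold=rare_threshold)
    if run_log is not None:
        run_log.append(
            f"rare motif exclusion: {res.n_excluded_units} motifs, "
            f"{res.excluded[CONTROL]} control and {res.excluded[CASE]} case copies "
            f"excluded; effective totals {res.effective_totals[CONTROL]} control, "
            f"{res.effective_totals[CASE]} case copies")
    rows, classes = [], {}
    for m in counts.index:
        total = int(counts.loc[m].sum())
        if m not in res.retained.index:
            classes[m] = "rare"
            continue
        r = virtual_reference_or(
            int(counts.loc[m, CASE]), res.effective_totals[CASE],
            int(counts.loc[m, CONTROL]), res.effective_totals[CONTROL], label=m)
        p_class = r.p
        if not math.isfinite(r.z):
            # group-exclusive motif: no Wald z; classify on the exact p
            exact = one_vs_rest_test(int(counts.loc[m, CASE]),
                                     int(counts.loc[m, CONTROL]),
                                     res.effective_totals[CASE],
                                     res.effective_totals[CONTROL],
                                     mode="fisher", label=m)
            p_class = exact.p
            r.p = exact.p
            r.method = "virtual_reference+fisher"
        r.classification = classify_motif(r.or_virtual, p_class, total,
                                          alpha=alpha, rare_threshold=rare_threshold)
        classes[m] = r.classification
        rows.append(r.as_dict())
    table = pd.DataFrame(rows).sort_values("z", ascending=False, na_position="last")
    return table.reset_index(drop=True), classes


def genotype_association_table(cohort_m: pd.DataFrame, rare_threshold: int = 5,
                               run_log: list | None = None) -> pd.DataFrame:
    """One-vs-rest genotype table with rare genotypes pooled into one
    retained category, using the virtual-genotype offset convention."""
    counts = (cohort_m.groupby(["genotype", "status"]).size()
              .unstack(fill_value=0))
    for col in (CONTROL, CASE):
        if col not in counts:
            counts[col] = 0
    pooled = pool_rare_genotypes(counts[[CONTROL, CASE]],
                                 threshold=rare_threshold)
    if run_log is not None:
        run_log.append(
            f"rare genotype pooling: {len(counts) - len(pooled) + 1} genotypes "
            f"pooled into 'rare' (threshold {rare_threshold} subjects)")
    n_cases = int((cohort_m["status"] == CASE).sum())
    n_controls = int((cohort_m["status"] == CONTROL).sum())
    rows = []
    for g, r in pooled.iterrows():
        if r[CASE] + r[CONTROL] == 0:
            continue
        res = one_vs_rest_test(int(r[CASE]), int(r[CONTROL]), n_cases, n_controls,
                               mode="logistic_offset", label=g)
        rows.append(res.as_dict())
    table = pd.DataFrame(rows).sort_values("z", ascending=False, na_position="last")
    return table.reset_index(drop=True)


def motif_tree(cohort_m: pd.DataFrame) -> tuple[str, object]:
    """Ward tree over the unique observed cis motifs (Levenshtein distances)."""
    motifs = sorted(set(cohort_m["motif_1"]) | set(cohort_m["motif_2"]))
    seqs = {m: m.replace("-", "") for m in motifs}
    dm = DistanceMatrix.from_sequences(seqs)
    tree = cluster(dm)
    return to_newick(tree), tree


def run_pipeline(cfg: PipelineConfig, cohort: pd.DataFrame | None = None,
                 registry=None, panel: ResiduePanel | None = None
                 ) -> PipelineResult:
    """Execute every analysis stage on a cohort and return the result bundle.

    ``cohort`` may be passed directly (e.g. from the simulator); otherwise it
    is read from ``cfg.cohort_path``.  Deterministic given the inputs.
    """
    run_log: list[str] = [f"dqmotif {__version__} config={cfg.config_hash()} "
                          f"seed={cfg.seed}"]
    panel = panel or ResiduePanel()
    try:
        if registry is None:
            registry = (load_registry(cfg.registry_path, panel)
                        if cfg.registry_path else load_default_registry(panel))
        if cohort is None:
            if cfg.cohort_path is None:
                raise ValueError("no cohort provided")
            cohort = load_cohort(cfg.cohort_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    if not cfg.phased:
        try:
            phased = phase_em(cohort, posterior_threshold=cfg.posterior_threshold)
        except Exception as exc:
            raise RuntimeError(f"stage 'phasing' failed: {exc}") from exc
        run_log.append(
            f"EM phasing: {phased.n_iter} iterations, min posterior "
            f"{phased.min_posterior:.4f}, {int(phased.assignments['flagged'].sum())} "
            f"subjects below {cfg.posterior_threshold}")
        keep = [c for c in cohort.columns if c not in
                ("dqa1_1", "dqb1_1", "dqa1_2", "dqb1_2")]
        cohort = phased.assignments.merge(cohort[keep], on="subject_id")
    else:
        run_log.append("phasing: pre-phased input accepted")

    try:
        cohort_m = attach_motifs(cohort, registry, panel)
    except Exception as exc:
        raise RuntimeError(f"stage 'motifs' failed: {exc}") from exc
    run_log.append(f"cohort: {int((cohort_m['status'] == CONTROL).sum())} controls, "
                   f"{int((cohort_m['status'] == CASE).sum())} cases")

    motif_table, classes = motif_association_table(
        cohort_m, cfg.rare_threshold, cfg.alpha, run_log)
    genotype_table = genotype_association_table(
        cohort_m, cfg.genotype_rare_threshold, run_log)

    try:
        group_table = genotype_group_analysis(cohort_m, classes)
    except Exception as exc:
        log.info("genotype-group analysis skipped: %s", exc)
        run_log.append(f"genotype-group analysis skipped: {exc}")
        group_table = None

    drdq = drdq_haplotype_analysis(cohort_m, min_copies=cfg.rare_threshold)
    run_log.append("DR-DQ haplotype analysis "
                   + ("done" if drdq is not None else "skipped (no DRB1)"))

    patients = cohort_m[cohort_m["status"] == CASE]
    ab_table = autoantibody_panel(patients, min_copies=cfg.antibody_min_copies)
    if len(ab_table) == 0:
        ab_table = None
        run_log.append("antibody analysis skipped (no antibody columns)")
    else:
        run_log.append(f"antibody analysis: {len(ab_table)} motif x antibody rows "
                       f"(min copies {cfg.antibody_min_copies})")

    try:
        af_table = af_pipeline(cohort_m, classes)
    except Exception as exc:
        log.info("AF analysis skipped: %s", exc)
        run_log.append(f"attributable-fraction analysis skipped: {exc}")
        af_table = None

    entropy = group_entropies(cohort_m, base=cfg.entropy_base)
    run_log.append(f"motif entropy: controls {entropy[CONTROL]:.3f}, "
                   f"cases {entropy[CASE]:.3f}")
    newick, _ = motif_tree(cohort_m)

    result = PipelineResult(motif_table, genotype_table, group_table, drdq,
                            ab_table, af_table, entropy, newick, classes, run_log)
    if cfg.output_dir:
        write_bundle(result, cfg.output_dir)
    return result


# display conventions: percentages and ORs to 2 decimals, p to 3 significant
# digits in scientific notation
_FORMATS = {"pct": "{:.2f}", "or": "{:.2f}", "p": "{:.3e}"}


def format_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col.endswith("_pct") or col in ("control_freq_pct", "case_freq_pct", "af_pct"):
            out[col] = out[col].map(lambda v: _FORMATS["pct"].format(v))
        elif col in ("or_virtual", "odds_ratio"):
            out[col] = out[col].map(lambda v: _FORMATS["or"].format(v))
        elif col == "p":
            out[col] = out[col].map(
                lambda v: _FORMATS["p"].format(v) if pd.notna(v) else "NA")
    return out


def write_bundle(result: PipelineResult, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "motif_association.tsv": result.motif_table,
        "genotype_association.tsv": result.genotype_table,
        "genotype_groups.tsv": result.genotype_group_table,
        "drdq_haplotypes.tsv": result.drdq_table,
        "antibody_association.tsv": result.antibody_table,
        "attributable_fractions.tsv": result.af_table,
    }
    for name, df in tables.items():
        if df is None:
            continue
        p = outdir / name
        format_table(df).to_csv(p, sep="\t", index=False)
        paths[name] = p
    (outdir / "motif_tree.nwk").write_text(result.newick + "\n")
    (outdir / "entropy.json").write_text(json.dumps(result.entropy, indent=2) + "\n")
    (outdir / "run_log.txt").write_text("\n".join(result.run_log) + "\n")
    paths["motif_tree.nwk"] = outdir / "motif_tree.nwk"
    return paths


def plot_motif_frequencies(motif_table: pd.DataFrame, path) -> None:
    """Simple grouped bar plot of motif frequencies among controls and cases."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = motif_table.sort_values("control_freq_pct", ascending=False)
    x = range(len(df))
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(df)), 4))
    ax.bar([i - 0.2 for i in x], df["control_freq_pct"], width=0.4, label="controls")
    ax.bar([i + 0.2 for i in x], df["case_freq_pct"], width=0.4, label="cases")
    ax.set_xticks(list(x))
    ax.set_xticklabels(df["label"], rotation=90, fontsize=7)
    ax.set_ylabel("motif frequency (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
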