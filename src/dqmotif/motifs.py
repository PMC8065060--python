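"""Motif engine: cis motifs, trans heterodimers, EM phasing, rare handling.

A DQ haplotype is a (DQA1, DQB1) allele pair on one chromosome; its *motif* is
the string of amino acids at the nine-residue panel, rendered "AAAA-BBBBB"
(four alpha residues, hyphen, five beta residues).  A subject carries two
haplotypes, hence a *motif genotype*.  Doubly heterozygous subjects can also
assemble two trans heterodimers by pairing an alpha chain from one chromosome
with a beta chain from the other; some such dimers are structurally
prohibited, which is expressed here through a user-supplied permissibility
lookup (all permitted by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .registry import AlleleRegistry, ResiduePanel, residue_at

CASE, CONTROL = "case", "control"

PHASED_COLUMNS = ["dqa1_1", "dqb1_1", "dqa1_2", "dqb1_2"]
UNPHASED_COLUMNS = ["dqa1_a", "dqa1_b", "dqb1_a", "dqb1_b"]
ANTIBODIES = ["iaa", "gada", "ia2a", "znt8ra", "znt8wa", "znt8qa"]


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class Haplotype:
    """A DQA1-DQB1 allele pairing; origin records whether it sits on one
    chromosome (cis) or was assembled across chromosomes (trans)."""

    dqa1: str
    dqb1: str
    origin: str = "cis"
    permitted: bool = True

    def __post_init__(self):
        if self.origin not in ("cis", "trans"):
            raise MotifError(f"unknown origin {self.origin!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.dqa1, self.dqb1)


@dataclass(frozen=True)
class Motif:
    """Nine panel residues; rendered with a hyphen between chains."""

    residues: str
    n_alpha: int = 4

    def __post_init__(self):
        if "-" in self.residues:
            raise MotifError("residues must be the bare residue string")

    @property
    def rendering(self) -> str:
        return f"{self.residues[:self.n_alpha]}-{self.residues[self.n_alpha:]}"

    @classmethod
    def from_string(cls, s: str) -> "Motif":
        if "-" in s:
            alpha, beta = s.split("-", 1)
            return cls(alpha + beta, n_alpha=len(alpha))
        return cls(s)

    def __str__(self) -> str:
        return self.rendering


def motif_of(hap: Haplotype, registry: AlleleRegistry, panel: ResiduePanel | None = None) -> Motif:
    """Extract the haplotype's motif in panel order."""
    panel = panel or ResiduePanel()
    alpha = registry.get(hap.dqa1)
    beta = registry.get(hap.dqb1)
    chars = [residue_at(alpha, p) for p in panel.alpha_positions]
    chars += [residue_at(beta, p) for p in panel.beta_positions]
    return Motif("".join(chars), n_alpha=len(panel.alpha_positions))


def motif_genotype(m1: str, m2: str) -> tuple[str, str]:
    """Canonical (lexicographically ordered) unordered motif pair."""
    return (m1, m2) if m1 <= m2 else (m2, m1)


def enumerate_heterodimers(h1: Haplotype, h2: Haplotype,
                           permissibility: dict[tuple[str, str], bool] | None = None
                           ) -> list[Haplotype]:
    """All distinct DQ molecules a phased haplotype pair can assemble.

    Doubly heterozygous genotypes yield up to four molecules (two cis, two
    trans); if either locus is homozygous the trans set coincides with the cis
    set.  Each molecule carries a cis/trans tag and a permitted flag looked up
    from ``permissibility`` (default: permitted).  Deduplication keeps the cis
    tag when the same allele pairing arises both ways.
    """
    permissibility = permissibility or {}
    candidates = [
        Haplotype(h1.dqa1, h1.dqb1, "cis"),
        Haplotype(h2.dqa1, h2.dqb1, "cis"),
        Haplotype(h1.dqa1, h2.dqb1, "trans"),
        Haplotype(h2.dqa1, h1.dqb1, "trans"),
    ]
    out: dict[tuple[str, str], Haplotype] = {}
    for hap in candidates:
        hap = replace(hap, permitted=permissibility.get(hap.key, True))
        if hap.key not in out:
            out[hap.key] = hap
        # cis listing takes precedence over a duplicate trans pairing
    return list(out.values())


# ---------------------------------------------------------------------------
# EM phasing of unphased two-locus genotypes
# ---------------------------------------------------------------------------

@dataclass
class PhaseAssignment:
    subject_id: object
    haplotypes: tuple[tuple[str, str], tuple[str, str]]
    posterior: float


@dataclass
class PhaseResult:
    assignments: pd.DataFrame  # subject_id, dqa1_1..dqb1_2, posterior
    frequencies: dict[tuple[str, str], float]
    log_likelihood: float
    n_iter: int
    converged: bool
    min_posterior: float


def _subject_configs(a1, a2, b1, b2):
    """The (at most two) phase configurations of a two-locus genotype."""
    c1 = ((a1, b1), (a2, b2))
    c2 = ((a1, b2), (a2, b1))
    if a1 == a2 or b1 == b2:
        return [c1]
    return [c1, c2]


def phase_em(cohort: pd.DataFrame, tol: float = 1e-8, max_iter: int = 500,
             posterior_threshold: float = 0.97) -> PhaseResult:
    """Maximum-likelihood two-locus haplotype phasing by EM.

    Haplotype frequencies are initialised from products of observed allele
    frequencies and updated until the log-likelihood improves by less than
    ``tol``.  Each double heterozygote's two phasings get posterior weights
    proportional to the products of the estimated haplotype frequencies;
    subjects below ``posterior_threshold`` are flagged (column ``flagged``).
    """
    missing = [c for c in UNPHASED_COLUMNS if c not in cohort.columns]
    if missing:
        raise MotifError(f"unphased cohort missing columns {missing}")
    if len(cohort) == 0:
        raise MotifError("empty cohort")

    geno = [
        _subject_configs(r.dqa1_a, r.dqa1_b, r.dqb1_a, r.dqb1_b)
        for r in cohort.itertuples()
    ]

    # initial frequencies: products of allele frequencies
    a_alleles = pd.concat([cohort["dqa1_a"], cohort["dqa1_b"]]).value_counts(normalize=True)
    b_alleles = pd.concat([cohort["dqb1_a"], cohort["dqb1_b"]]).value_counts(normalize=True)
    haps = sorted({h for configs in geno for c in configs for h in c})
    freq = {h: float(a_alleles[h[0]] * b_alleles[h[1]]) for h in haps}
    total = sum(freq.values())
    freq = {h: f / total for h, f in freq.items()}

    n = len(geno)
    loglik = -math.inf
    converged = False
    for it in range(1, max_iter + 1):
        counts = dict.fromkeys(freq, 0.0)
        new_loglik = 0.0
        for configs in geno:
            weights = [freq[h1] * freq[h2] for h1, h2 in configs]
            s = sum(weights)
            if s <= 0:
                # all configurations currently impossible; spread evenly
                weights = [1.0] * len(configs)
                s = float(len(configs))
                new_loglik += -745.0  # log of ~5e-324, effectively impossible
            else:
                new_loglik += math.log(s)
            for (h1, h2), w in zip(configs, weights):
                counts[h1] += w / s
                counts[h2] += w / s
        freq = {h: c / (2 * n) for h, c in counts.items()}
        if new_loglik - loglik < tol and new_loglik >= loglik:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    n_iter = it

    rows = []
    min_post = 1.0
    ids = cohort["subject_id"] if "subject_id" in cohort.columns else cohort.index
    for sid, configs in zip(ids, geno):
        weights = [freq[h1] * freq[h2] for h1, h2 in configs]
        s = sum(weights)
        if len(configs) == 1:
            best, post = configs[0], 1.0
        elif s <= 0:
            best, post = configs[0], 0.5
        else:
            i = int(np.argmax(weights))
            best, post = configs[i], weights[i] / s
        min_post = min(min_post, post)
        (a1, b1), (a2, b2) = best
        rows.append({"subject_id": sid, "dqa1_1": a1, "dqb1_1": b1,
                     "dqa1_2": a2, "dqb1_2": b2, "posterior": post,
                     "flagged": post < posterior_threshold})
    assignments = pd.DataFrame(rows)
    return PhaseResult(assignments, freq, loglik, n_iter, converged, min_post)


# ---------------------------------------------------------------------------
# Cohort -> motifs
# ---------------------------------------------------------------------------

def cohort_haplotypes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Long table of cis haplotype copies: subject_id, status, dqa1, dqb1, drb1."""
    missing = [c for c in PHASED_COLUMNS if c not in cohort.columns]
    if missing:
        raise MotifError(f"phased cohort missing columns {missing} (run phase_em first?)")
    frames = []
    for i in (1, 2):
        cols = {"subject_id": cohort.get("subject_id", cohort.index),
                "status": cohort["status"],
                "dqa1": cohort[f"dqa1_{i}"], "dqb1": cohort[f"dqb1_{i}"]}
        if f"drb1_{i}" in cohort.columns:
            cols["drb1"] = cohort[f"drb1_{i}"]
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def attach_motifs(cohort: pd.DataFrame, registry: AlleleRegistry,
                  panel: ResiduePanel | None = None) -> pd.DataFrame:
    """Add motif_1, motif_2 (rendered) and the canonical genotype column."""
    panel = panel or ResiduePanel()
    out = cohort.copy()
    cache: dict[tuple[str, str], str] = {}

    def render(a, b):
        key = (a, b)
        if key not in cache:
            cache[key] = motif_of(Haplotype(a, b), registry, panel).rendering
        return cache[key]

    out["motif_1"] = [render(a, b) for a, b in zip(out["dqa1_1"], out["dqb1_1"])]
    out["motif_2"] = [render(a, b) for a, b in zip(out["dqa1_2"], out["dqb1_2"])]
    pairs = [motif_genotype(m1, m2) for m1, m2 in zip(out["motif_1"], out["motif_2"])]
    out["genotype"] = [f"{m1}/{m2}" for m1, m2 in pairs]
    return out


def motif_copy_counts(cohort_with_motifs: pd.DataFrame) -> pd.DataFrame:
    """Copies of each motif per group (columns 'control', 'case')."""
    long = pd.concat([
        cohort_with_motifs[["status", "motif_1"]].rename(columns={"motif_1": "motif"}),
        cohort_with_motifs[["status", "motif_2"]].rename(columns={"motif_2": "motif"}),
    ])
    counts = long.groupby(["motif", "status"]).size().unstack(fill_value=0)
    for col in (CONTROL, CASE):
        if col not in counts.columns:
            counts[col] = 0
    return counts[[CONTROL, CASE]].sort_index()


@dataclass
class CollapseResult:
    retained: pd.DataFrame          # counts per motif per group
    excluded: dict[str, int]        # copies excluded per group
    effective_totals: dict[str, int]  # 2N - excluded per group
    n_excluded_units: int           # number of rare units removed


def collapse_rare(counts: pd.DataFrame, threshold: int = 5) -> CollapseResult:
    """Drop units with fewer than ``threshold`` total copies across groups.

    Returns the retained counts, the excluded copy tally per group, and the
    effective totals (column sums after exclusion, i.e. 2N minus exclusions).
    """
    if threshold < 1:
        raise MotifError("threshold must be >= 1")
    total = counts.sum(axis=1)
    rare = total < threshold
    retained = counts.loc[~rare]
    excluded = {c: int(counts.loc[rare, c].sum()) for c in counts.columns}
    eff = {c: int(retained[c].sum()) for c in counts.columns}
    return CollapseResult(retained, excluded, eff, int(rare.sum()))


def pool_rare_genotypes(counts: pd.DataFrame, threshold: int = 5,
                        label: str = "rare") -> pd.DataFrame:
    """Merge genotypes with < ``threshold`` total observations into one
    retained 'rare' category (genotype-table behaviour, unlike motif-level
    exclusion)."""
    total = counts.sum(axis=1)
    rare = total < threshold
    pooled = counts.loc[~rare].copy()
    if rare.any():
        pooled.loc[label] = counts.loc[rare].sum()
    return pooled


RISK, RESISTANT, NEUTRAL, RARE = "risk", "resistant", "neutral", "rare"


def classify_motif(or_value: float, p: float, copies: int,
                   alpha: float = 0.05, rare_threshold: int = 5) -> str:
    """Susceptibility class: rare takes precedence; then significant
    OR > 1 -> risk, significant OR < 1 -> resistant, otherwise neutral."""
    if copies < rare_threshold:
        return RARE
    if p is not None and not np.isnan(p) and p < alpha:
        if or_value > 1:
            return RISK
        if or_value < 1:
            return RESISTANT
    return NEUTRAL
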