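"""Diversity entropy, attributable fractions and OR-additivity diagnostics.

Shannon entropy H = -sum f_j log f_j over category frequencies quantifies the
diversity of the motif pool in each group (natural log by default, so the
maximum over q categories is log q nats).

The attributable fraction of a genotype group with control frequency f and
odds ratio OR is

    AF = f (OR - 1) / (1 + f |OR - 1|),

positive for risk groups (attributable risk fraction) and negative for
protective ones (attributable protective fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .motifs import CASE, CONTROL, RISK, RESISTANT, NEUTRAL, motif_genotype


class SummaryError(ValueError):
    pass


def shannon_entropy(frequencies, base: float = math.e) -> float:
    """Entropy of a frequency vector.  Zero-frequency entries are dropped;
    frequencies must sum to 1 (tolerance 1e-9 relative)."""
    f = np.asarray(list(frequencies), dtype=float)
    if np.any(f < 0):
        raise SummaryError("negative frequency")
    if abs(f.sum() - 1.0) > 1e-6:
        raise SummaryError(f"frequencies sum to {f.sum():.6f}, not 1")
    f = f[f > 0]
    h = float(-(f * np.log(f)).sum())
    return h / math.log(base)


@dataclass
class AFResult:
    group: str
    f: float             # control-estimated genotype-group frequency
    odds_ratio: float
    af: float

    @property
    def kind(self) -> str:
        return "risk" if self.af > 0 else ("protective" if self.af < 0 else "null")


def attributable_fraction(f: float, odds_ratio: float, group: str = "") -> AFResult:
    """AF = f(OR-1) / (1 + f|OR-1|); sign follows the direction of effect."""
    if not 0 <= f <= 1:
        raise SummaryError(f"frequency {f} outside [0,1]")
    if not odds_ratio > 0:
        raise SummaryError(f"odds ratio must be positive, got {odds_ratio}")
    af = f * (odds_ratio - 1) / (1 + f * abs(odds_ratio - 1))
    return AFResult(group, f, odds_ratio, af)


# genotype-group labels in display order; neutral/neutral is the reference
AF_GROUPS = ["resistant/resistant", "neutral/resistant", "neutral/neutral",
             "neutral/risk", "risk/risk", "resistant/risk"]


def genotype_group_of(class1: str, class2: str) -> str:
    """Pooled genotype group of a motif-class pair (rare treated as neutral
    for pooling purposes)."""
    def norm(c):
        return NEUTRAL if c not in (RISK, RESISTANT) else c
    a, b = sorted((norm(class1), norm(class2)))
    return f"{a}/{b}"


def af_pipeline(cohort_with_motifs: pd.DataFrame,
                classes: dict[str, str]) -> pd.DataFrame:
    """Attributable fractions per pooled genotype group.

    Motifs are pooled into resistant / neutral / risk; each subject's pair of
    pooled classes defines one of six genotype groups.  A logistic regression
    of status on the five non-reference group indicators (reference:
    neutral/neutral homozygotes) yields per-group log odds ratios; group
    frequencies are estimated from the controls; AF follows the closed form.
    """
    df = cohort_with_motifs
    group = [
        genotype_group_of(classes.get(m1, NEUTRAL), classes.get(m2, NEUTRAL))
        for m1, m2 in (motif_genotype(a, b) for a, b in zip(df["motif_1"], df["motif_2"]))
    ]
    group = pd.Series(group, index=df.index, name="group")
    y = (df["status"] == CASE).astype(float)

    ref = "neutral/neutral"
    if not (group == ref).any():
        raise SummaryError("no neutral/neutral reference subjects")
    present = [g for g in AF_GROUPS if g != ref and (group == g).any()]
    X = pd.DataFrame({g: (group == g).astype(float) for g in present})
    X = sm.add_constant(X, has_constant="add")
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)

    controls = group[df["status"] == CONTROL]
    n_controls = len(controls)
    rows = []
    for g in present:
        coef = float(fit.params[g])
        se = float(fit.bse[g])
        orv = math.exp(coef)
        f = float((controls == g).sum()) / n_controls
        af = attributable_fraction(f, orv, group=g)
        z = coef / se if se > 0 else math.nan
        rows.append({"group": g, "control_freq_pct": 100 * f,
                     "coef": coef, "se": se, "z": z,
                     "p": float(fit.pvalues[g]), "odds_ratio": orv,
                     "af_pct": 100 * af.af})
    return pd.DataFrame(rows)


def or_product_check(or_a: float, or_b: float, or_ab: float) -> dict:
    """Multiplicativity diagnostic: under additivity on the logit scale the
    doubly-heterozygous OR should equal the product of the two single-motif
    (heterozygote-with-neutral) ORs; the ratio or_ab/(or_a*or_b) is near 1
    when the effects combine multiplicatively."""
    for v in (or_a, or_b, or_ab):
        if not v > 0:
            raise SummaryError("odds ratios must be positive")
    product = or_a * or_b
    return {"product": product, "ratio": or_ab / product}


def group_entropies(cohort_with_motifs: pd.DataFrame, base: float = math.e,
                    rare_threshold: int = 0) -> dict[str, float]:
    """Shannon entropy of the motif pool among controls and among cases.

    ``rare_threshold`` > 0 excludes motifs with fewer total copies before
    normalising, mirroring the motif-table exclusion.
    """
    from .motifs import motif_copy_counts, collapse_rare
    counts = motif_copy_counts(cohort_with_motifs)
    if rare_threshold > 0:
        counts = collapse_rare(counts, threshold=rare_threshold).retained
    out = {}
    for grp in (CONTROL, CASE):
        col = counts[grp]
        col = col[col > 0]
        out[grp] = shannon_entropy((col / col.sum()).to_numpy(), base=base)
    return out
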