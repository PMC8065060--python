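"""Association statistics for motif, genotype, haplotype and antibody analyses.

Two odds-ratio conventions coexist and are always labelled:

``or_virtual``
    The virtual-reference convention: an imaginary reference haplotype with
    equal frequency in cases and controls has OR 1, so any unit's OR is simply
    the ratio of its case and control frequencies.  This is the convention the
    motif/haplotype tables print.

``or_2x2``
    The familiar cross-product (or conditional-MLE) odds ratio of a 2x2 table,
    used by the one-vs-rest genotype comparisons.

Z statistics are Wald statistics on the log scale.  Exact p-values come from
Fisher's test (two-sided by summing hypergeometric probabilities no larger
than the observed table's).  No multiple-testing correction is applied
anywhere by default; :func:`bh_adjust` exists as an opt-in utility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio
import statsmodels.api as sm

from .motifs import (CASE, CONTROL, RISK, RESISTANT, NEUTRAL,
                     cohort_haplotypes, motif_genotype)

log = logging.getLogger("dqmotif")

OR_CASE_ONLY = math.inf  # unit absent among controls
OR_CONTROL_ONLY = 0.0    # unit absent among cases


class StatsError(ValueError):
    pass


@dataclass
class AssociationResult:
    label: str
    control_count: int
    case_count: int
    control_total: int
    case_total: int
    or_virtual: float
    z: float
    p: float
    method: str = "virtual_reference"
    classification: str | None = None

    @property
    def control_freq(self) -> float:
        return self.control_count / self.control_total

    @property
    def case_freq(self) -> float:
        return self.case_count / self.case_total

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "control_count": self.control_count, "case_count": self.case_count,
            "control_freq_pct": 100 * self.control_freq,
            "case_freq_pct": 100 * self.case_freq,
            "or_virtual": self.or_virtual, "z": self.z, "p": self.p,
            "method": self.method, "classification": self.classification,
        }


def virtual_reference_or(case_count: int, case_total: int,
                         control_count: int, control_total: int,
                         label: str = "") -> AssociationResult:
    """Frequency-ratio odds ratio against the virtual reference haplotype.

    OR = (case_count/case_total) / (control_count/control_total).  The Wald
    standard error of the log frequency ratio under multinomial sampling is
    sqrt(1/a - 1/case_total + 1/c - 1/control_total).  Units absent from one
    group get a directional sentinel (0 or inf) with z/p undefined.
    """
    if case_total <= 0 or control_total <= 0:
        raise StatsError("group totals must be positive")
    a, c = int(case_count), int(control_count)
    if a == 0 and c == 0:
        raise StatsError(f"unit {label!r} observed in neither group")
    if a == 0:
        return AssociationResult(label, c, a, control_total, case_total,
                                 OR_CONTROL_ONLY, math.nan, math.nan)
    if c == 0:
        return AssociationResult(label, c, a, control_total, case_total,
                                 OR_CASE_ONLY, math.nan, math.nan)
    or_v = (a / case_total) / (c / control_total)
    se = math.sqrt(1 / a - 1 / case_total + 1 / c - 1 / control_total)
    z = math.log(or_v) / se
    p = 2 * sps.norm.sf(abs(z))
    return AssociationResult(label, c, a, control_total, case_total, or_v, z, p)


def virtual_or_clustered(cohort_with_motifs: pd.DataFrame, motif: str
                         ) -> AssociationResult:
    """Virtual-reference OR for one motif with a subject-clustered SE.

    A subject contributes two (correlated) motif copies; the plain multinomial
    copy-level variance understates uncertainty whenever carriage clusters
    within subjects.  Here Var(p-hat) per group is estimated from the
    between-subject variance of per-subject copy counts, giving
    Var(log OR) = sum_g Var(p-hat_g) / p-hat_g^2.
    """
    df = cohort_with_motifs
    parts = {}
    for grp in (CASE, CONTROL):
        sub = df[df["status"] == grp]
        k = ((sub["motif_1"] == motif).astype(int)
             + (sub["motif_2"] == motif).astype(int)).to_numpy(dtype=float)
        n = len(sub)
        total = 2 * n
        count = float(k.sum())
        phat = count / total
        var_sum = float(((k - 2 * phat) ** 2).sum())
        parts[grp] = (count, total, phat, var_sum / total**2)
    (a, case_total, pc, vc) = parts[CASE]
    (c, control_total, pk, vk) = parts[CONTROL]
    if a == 0 or c == 0:
        return virtual_reference_or(int(a), case_total, int(c), control_total,
                                    label=motif)
    or_v = pc / pk
    se = math.sqrt(vc / pc**2 + vk / pk**2)
    z = math.log(or_v) / se
    p = 2 * sps.norm.sf(abs(z))
    res = AssociationResult(motif, int(c), int(a), control_total, case_total,
                            or_v, z, p, method="virtual_reference_clustered")
    return res


# ---------------------------------------------------------------------------
# One-vs-rest 2x2 analyses
# ---------------------------------------------------------------------------

@dataclass
class GenotypeGroupResult:
    label: str
    case_count: int
    case_total: int
    control_count: int
    control_total: int
    coef: float
    se: float
    z: float
    p: float
    method: str
    ci95: tuple[float, float] | None = None
    classification: str | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.coef) if math.isfinite(self.coef) else (
            math.inf if self.coef > 0 else 0.0)

    @property
    def case_freq(self) -> float:
        return self.case_count / self.case_total

    @property
    def control_freq(self) -> float:
        return self.control_count / self.control_total

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "control_count": self.control_count,
            "control_freq_pct": 100 * self.control_freq,
            "case_count": self.case_count,
            "case_freq_pct": 100 * self.case_freq,
            "coef": self.coef, "se": self.se, "z": self.z, "p": self.p,
            "odds_ratio": self.odds_ratio, "method": self.method,
            "classification": self.classification,
        }


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    tables (with the observed margins) no more probable than the observed."""
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def one_vs_rest_test(unit_case: int, unit_control: int,
                     case_total: int, control_total: int,
                     mode: str = "fisher", label: str = "") -> GenotypeGroupResult:
    """Compare one unit's counts against all other units combined.

    ``fisher`` mode: conditional-MLE odds ratio with an exact two-sided p.
    ``logistic_offset`` mode: an intercept-free binomial fit with constant
    offset logit(case_total/(case_total+control_total)); its ML coefficient is
    exactly the log frequency-ratio (virtual-reference) odds ratio and its
    standard error is sqrt(1/a + 1/c).  Zero cells in this mode fall back to
    the exact test with a directional OR sentinel (separation handling).
    """
    a, c = int(unit_case), int(unit_control)
    b, d = int(case_total) - a, int(control_total) - c
    if min(a + c, b + d, a + b, c + d) < 0 or (a + b <= 0 or c + d <= 0):
        raise StatsError("degenerate 2x2 table")
    if (a + c) == 0:
        raise StatsError(f"unit {label!r} unobserved")

    if mode == "fisher":
        res = _odds_ratio([[a, b], [c, d]], kind="conditional")
        p = fisher_two_sided(a, b, c, d)
        orv = float(res.statistic)
        ci = res.confidence_interval(0.95)
        coef = math.log(orv) if 0 < orv < math.inf else (
            -math.inf if orv == 0 else math.inf)
        z = sps.norm.isf(p / 2) * (1 if coef >= 0 else -1) if 0 < p < 1 else math.nan
        return GenotypeGroupResult(label, a, case_total, c, control_total,
                                   coef, math.nan, z, p, "fisher",
                                   ci95=(float(ci.low), float(ci.high)))
    if mode == "logistic_offset":
        if a == 0 or c == 0:
            res = one_vs_rest_test(a, c, case_total, control_total,
                                   mode="fisher", label=label)
            res.method = "fisher(separation)"
            return res
        coef = math.log((a / case_total) / (c / control_total))
        se = math.sqrt(1 / a + 1 / c)
        z = coef / se
        p = 2 * sps.norm.sf(abs(z))
        return GenotypeGroupResult(label, a, case_total, c, control_total,
                                   coef, se, z, p, "logistic_offset")
    raise StatsError(f"unknown mode {mode!r}")


def one_vs_rest_subject(a: int, c: int, n_cases: int, n_controls: int,
                        label: str = "") -> GenotypeGroupResult:
    """Subject-level univariate logistic fit of status on a genotype indicator.

    With a single binary covariate the ML estimates are available in closed
    form: coef = log cross-product OR, se = sqrt(sum of reciprocal cells).
    Zero cells are reported through the exact test instead (separation).
    """
    b, d = n_cases - a, n_controls - c
    if min(a, b, c, d) < 0:
        raise StatsError("negative cell")
    if 0 in (a, b, c, d):
        res = one_vs_rest_test(a, c, n_cases, n_controls, mode="fisher", label=label)
        res.method = "fisher(separation)"
        if a == 0 and c >= 5:
            res.classification = "highly_resistant"
        return res
    coef = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = coef / se
    p = 2 * sps.norm.sf(abs(z))
    return GenotypeGroupResult(label, a, n_cases, c, n_controls,
                               coef, se, z, p, "logistic")


# ---------------------------------------------------------------------------
# Genotype-group pairing analysis (risk motif x {neutral, self, risk, resistant})
# ---------------------------------------------------------------------------

def genotype_group_analysis(cohort_with_motifs: pd.DataFrame,
                            classes: dict[str, str]) -> pd.DataFrame:
    """Pair each risk motif with neutral motifs, itself, other risk motifs and
    resistant motifs, and test each resulting genotype one-vs-rest at the
    subject level."""
    df = cohort_with_motifs
    risks = sorted(m for m, c in classes.items() if c == RISK)
    if not risks:
        raise StatsError("no risk motifs in class assignment")

    def cls(m):
        return classes.get(m, "rare")

    pairs = [motif_genotype(m1, m2) for m1, m2 in zip(df["motif_1"], df["motif_2"])]
    pair_class = [(pair, (cls(pair[0]), cls(pair[1]))) for pair in pairs]
    status = df["status"].to_numpy()
    n_cases = int((status == CASE).sum())
    n_controls = int((status == CONTROL).sum())

    categories: list[tuple[str, object]] = []
    for r in risks:
        categories.append((
            f"{r}/neutral",
            lambda pair, kls, r=r: r in pair and (
                (pair[0] == r and kls[1] == NEUTRAL and pair[1] != r) or
                (pair[1] == r and kls[0] == NEUTRAL and pair[0] != r)),
        ))
        categories.append((f"{r}/{r}", lambda pair, kls, r=r: pair == (r, r)))
    for i, r1 in enumerate(risks):
        for r2 in risks[i + 1:]:
            categories.append((
                f"{r1}/{r2}",
                lambda pair, kls, g=motif_genotype(r1, r2): pair == g,
            ))
    for r in risks:
        categories.append((
            f"{r}/resistant",
            lambda pair, kls, r=r: r in pair and (
                (pair[0] == r and kls[1] == RESISTANT) or
                (pair[1] == r and kls[0] == RESISTANT and pair[0] != r)),
        ))

    rows = []
    for name, member in categories:
        inset = np.array([member(pair, kls) for pair, kls in pair_class])
        a = int((inset & (status == CASE)).sum())
        c = int((inset & (status == CONTROL)).sum())
        if a + c == 0:
            log.info("genotype group %s has no members; row omitted", name)
            continue
        rows.append(one_vs_rest_subject(a, c, n_cases, n_controls, label=name).as_dict())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Conditional (adjusted) scans
# ---------------------------------------------------------------------------

def motif_design(cohort_with_motifs: pd.DataFrame,
                 reference: str | None = None) -> pd.DataFrame:
    """Per-subject cis-motif copy counts (0/1/2), one column per motif, with
    the reference motif (default: most common) dropped to avoid the
    counts-sum-to-two collinearity with an intercept."""
    df = cohort_with_motifs
    motifs = pd.concat([df["motif_1"], df["motif_2"]])
    order = motifs.value_counts().index.tolist()
    reference = reference or order[0]
    cols = {}
    for m in order:
        if m == reference:
            continue
        cols[m] = ((df["motif_1"] == m).astype(int) + (df["motif_2"] == m).astype(int))
    return pd.DataFrame(cols, index=df.index)


def trans_motif_design(cohort_with_motifs: pd.DataFrame, registry, panel) -> pd.DataFrame:
    """Per-subject counts of *novel* trans motifs (trans pairings whose motif
    differs from both cis motifs)."""
    from .motifs import Haplotype, enumerate_heterodimers, motif_of

    df = cohort_with_motifs
    cols: dict[str, np.ndarray] = {}
    values: dict[str, list] = {}
    for idx, r in enumerate(df.itertuples()):
        h1 = Haplotype(r.dqa1_1, r.dqb1_1)
        h2 = Haplotype(r.dqa1_2, r.dqb1_2)
        cis = {r.motif_1, r.motif_2}
        for hap in enumerate_heterodimers(h1, h2):
            if hap.origin != "trans":
                continue
            m = motif_of(hap, registry, panel).rendering
            if m in cis:
                continue
            values.setdefault(m, []).append(idx)
    n = len(df)
    for m, idxs in values.items():
        col = np.zeros(n, dtype=int)
        for i in idxs:
            col[i] += 1
        cols[m] = col
    return pd.DataFrame(cols, index=df.index)


def _fit_glm(y, X, offset=None):
    model = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
    return model.fit(maxiter=200)


@dataclass
class ConditionalResult:
    term: str
    copies: int
    coef: float
    se: float
    z: float
    p_adjusted: float
    p_marginal: float
    status: str = "ok"

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def conditional_scan(y, adjust: pd.DataFrame,
                     test_terms: dict[str, pd.Series | pd.DataFrame],
                     min_copies: int = 5) -> pd.DataFrame:
    """Two-step conditional association scan.

    Step one fits logit Pr(Y=1) = adjust(X, beta); step two tests each term Z
    holding that adjustment component fixed, via the efficient score test at
    gamma = 0: U = Z'(y - p-hat) with variance V = Z'WZ - Z'WX (X'WX)^-1
    X'WZ (the projection term accounts for beta having been estimated, which
    keeps the test calibrated when Z is correlated with the adjustment
    design).  The adjusted coefficient reported alongside is the offset-fit
    gamma-hat.  Multi-column terms get a chi-square score statistic with one
    degree of freedom per column.  The marginal (unadjusted) p for the same
    term is reported for comparison.  Terms collinear with the adjustment
    design are reported as confounded (coef 0, p NA); terms with fewer than
    ``min_copies`` total copies are skipped.
    """
    y = np.asarray(y, dtype=float)
    Xa = sm.add_constant(np.asarray(adjust, dtype=float), has_constant="add")
    base = _fit_glm(y, Xa)
    offset = np.asarray(Xa @ base.params)
    p0 = 1 / (1 + np.exp(-offset))
    w = p0 * (1 - p0)
    XtWX_inv = np.linalg.pinv(Xa.T @ (Xa * w[:, None]))

    rows = []
    for name, term in test_terms.items():
        Z = np.asarray(term, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        copies = int(Z.sum())
        if copies < min_copies:
            rows.append(ConditionalResult(name, copies, math.nan, math.nan,
                                          math.nan, math.nan, math.nan,
                                          "skipped(<min_copies)").as_dict())
            continue
        # collinearity of the term with the adjustment design
        beta_hat, *_ = np.linalg.lstsq(Xa, Z, rcond=None)
        resid = Z - Xa @ beta_hat
        denom = np.linalg.norm(Z) or 1.0
        if np.linalg.norm(resid) / denom < 1e-8:
            rows.append(ConditionalResult(name, copies, 0.0, math.nan, math.nan,
                                          math.nan, _marginal_p(y, Z),
                                          "confounded").as_dict())
            continue
        U = Z.T @ (y - p0)
        ZtWX = Z.T @ (Xa * w[:, None])
        V = Z.T @ (Z * w[:, None]) - ZtWX @ XtWX_inv @ ZtWX.T
        try:
            if Z.shape[1] == 1:
                v = float(V[0, 0])
                if v <= 0:
                    raise np.linalg.LinAlgError("non-positive score variance")
                z = float(U[0]) / math.sqrt(v)
                p_adj = 2 * sps.norm.sf(abs(z))
                fit = _fit_glm(y, Z, offset=offset)
                coef = float(fit.params[0])
                se = abs(coef / z) if z != 0 else float(fit.bse[0])
            else:
                stat = float(U.T @ np.linalg.solve(V, U))
                p_adj = float(sps.chi2.sf(stat, df=Z.shape[1]))
                coef, se, z = math.nan, math.nan, math.nan
            rows.append(ConditionalResult(name, copies, coef, se, z, p_adj,
                                          _marginal_p(y, Z)).as_dict())
        except Exception as exc:  # separation or singular variance
            log.info("conditional fit for %s failed: %s", name, exc)
            rows.append(ConditionalResult(name, copies, math.nan, math.nan,
                                          math.nan, math.nan,
                                          _marginal_p(y, Z), "separated").as_dict())
    return pd.DataFrame(rows)


def _marginal_p(y, Z) -> float:
    """Unadjusted p for the same term (Wald for one column, LRT otherwise)."""
    X = sm.add_constant(Z, has_constant="add")
    try:
        fit = _fit_glm(y, X)
    except Exception:
        return math.nan
    if Z.shape[1] == 1:
        se = float(fit.bse[1])
        if not math.isfinite(se) or se <= 0 or se > 1e3:
            return math.nan
        return float(2 * sps.norm.sf(abs(fit.params[1] / se)))
    null = _fit_glm(y, np.ones((len(y), 1)))
    return float(sps.chi2.sf(2 * (fit.llf - null.llf), df=Z.shape[1]))


def residue_design(cohort: pd.DataFrame, registry, positions=None,
                   panel=None) -> dict[str, pd.DataFrame]:
    """Per-residue amino-acid copy-count designs across a cohort's haplotypes.

    For each polymorphic position, returns a design with one count column per
    amino acid minus the most common one (the within-position baseline).
    """
    from .registry import polymorphic_positions, residue_at as _res

    haps = list(zip(
        pd.concat([cohort["dqa1_1"], cohort["dqa1_2"]]),
        pd.concat([cohort["dqb1_1"], cohort["dqb1_2"]]),
    ))
    if positions is None:
        positions = polymorphic_positions(registry, set(haps))
    designs: dict[str, pd.DataFrame] = {}
    n = len(cohort)
    for pos in positions:
        counts: dict[str, np.ndarray] = {}
        for j in (1, 2):
            col = "dqa1" if pos.chain == "alpha" else "dqb1"
            alleles = cohort[f"{col}_{j}"]
            aas = [_res(registry.get(a), pos) for a in alleles]
            for i, aa in enumerate(aas):
                counts.setdefault(aa, np.zeros(n, dtype=int))[i] += 1
        if len(counts) < 2:
            continue
        baseline = max(counts, key=lambda aa: counts[aa].sum())
        cols = {f"{pos}{aa}": v for aa, v in counts.items() if aa != baseline}
        designs[str(pos)] = pd.DataFrame(cols, index=cohort.index)
    return designs


# ---------------------------------------------------------------------------
# Autoantibody associations (patients only)
# ---------------------------------------------------------------------------

def _motif_outcome_table(patients: pd.DataFrame, outcome: pd.Series,
                         min_copies: int) -> list[tuple[str, int, int, int, int]]:
    """Per-motif copy counts split by a binary patient-level outcome.

    Returns (motif, positive copies of motif, negative copies of motif,
    total positive copies, total negative copies) for motifs with more than
    ``min_copies`` copies among outcome-informative patients.
    """
    ok = outcome.notna()
    sub = patients.loc[ok]
    out = outcome.loc[ok].astype(int)
    long = pd.concat([
        pd.DataFrame({"motif": sub["motif_1"], "y": out}),
        pd.DataFrame({"motif": sub["motif_2"], "y": out}),
    ])
    tot = long.groupby("motif").size()
    pos = long.groupby("motif")["y"].sum()
    K = int(long["y"].sum())
    N = int(len(long))
    rows = []
    for m in tot.index:
        if tot[m] <= min_copies:
            continue
        a = int(pos[m])
        rows.append((m, a, int(tot[m]) - a, K, N - K))
    return rows


def _score_test(a, b, K, N) -> tuple[float, float]:
    """Hypergeometric score z for a 2x2 (motif vs rest) x (pos vs neg) split.

    a = positive copies of the motif, b = negative copies, K = all positive
    copies, N = all copies."""
    n_m = a + b
    if N <= 1 or K == 0 or K == N or n_m == N:
        return math.nan, math.nan
    e = n_m * K / N
    v = n_m * K * (N - n_m) * (N - K) / (N**2 * (N - 1))
    if v <= 0:
        return math.nan, math.nan
    z = (a - e) / math.sqrt(v)
    return z, 2 * sps.norm.sf(abs(z))


def autoantibody_association(patients: pd.DataFrame, antibody: str,
                             min_copies: int = 10) -> pd.DataFrame | None:
    """Association of each motif with positivity for one autoantibody.

    Units are motif copies among patients with a non-missing call; missing
    calls are excluded (not treated as negative).  One-vs-rest 2x2 per motif
    with a hypergeometric score z and cross-product OR; motifs with at most
    ``min_copies`` copies are skipped.  Returns None (with a notice) when the
    antibody column is absent.
    """
    if antibody not in patients.columns:
        log.info("antibody column %s absent; skipped", antibody)
        return None
    calls = pd.to_numeric(patients[antibody], errors="coerce")
    rows = []
    for m, a, b, K, notK in _motif_outcome_table(patients, calls, min_copies):
        N = K + notK
        z, p = _score_test(a, b, K, N)
        c, d = K - a, notK - b
        if min(a, b, c, d) > 0:
            orv = (a * d) / (b * c)
        elif a + c == 0 or b + d == 0:
            orv = math.nan
        else:
            orv = OR_CASE_ONLY if (b == 0 or c == 0) else OR_CONTROL_ONLY
        rows.append({"motif": m, "antibody": antibody, "copies": a + b,
                     "positive_copies": a, "odds_ratio": orv, "z": z, "p": p})
    return pd.DataFrame(rows)


def autoantibody_panel(patients: pd.DataFrame, antibodies=None,
                       min_copies: int = 10) -> pd.DataFrame:
    """Motif x antibody association table over the measured antibody panel."""
    from .motifs import ANTIBODIES
    frames = []
    for ab in antibodies or ANTIBODIES:
        res = autoantibody_association(patients, ab, min_copies=min_copies)
        if res is not None and len(res):
            frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["motif", "antibody", "copies",
                                     "positive_copies", "odds_ratio", "z", "p"])
    return pd.concat(frames, ignore_index=True)


def autoantibody_count_contrast(patients: pd.DataFrame, antibodies=None,
                                min_copies: int = 10) -> pd.DataFrame:
    """Contrast patients with 2-4 positive autoantibodies against those with
    0-1, per motif.  Patients with all calls missing are excluded."""
    from .motifs import ANTIBODIES
    abs_ = [ab for ab in (antibodies or ANTIBODIES) if ab in patients.columns]
    if not abs_:
        raise StatsError("no antibody columns present")
    calls = patients[abs_].apply(pd.to_numeric, errors="coerce")
    n_pos = calls.sum(axis=1, skipna=True)
    all_missing = calls.isna().all(axis=1)
    outcome = (n_pos >= 2).astype(float)
    outcome[all_missing] = np.nan
    rows = []
    for m, a, b, K, notK in _motif_outcome_table(patients, outcome, min_copies):
        N = K + notK
        z, p = _score_test(a, b, K, N)
        c, d = K - a, notK - b
        orv = (a * d) / (b * c) if min(a, b, c, d) > 0 else math.nan
        rows.append({"motif": m, "contrast": "2-4_vs_0-1", "copies": a + b,
                     "multi_ab_copies": a, "odds_ratio": orv, "z": z, "p": p})
    return pd.DataFrame(rows)


def antibody_count_group(calls: list) -> str | None:
    """Group label for one patient's antibody calls: '2-4', '0-1', or None if
    every call is missing."""
    vals = [v for v in calls if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not vals:
        return None
    return "2-4" if sum(vals) >= 2 else "0-1"


# ---------------------------------------------------------------------------
# DR-DQ joint haplotype analysis
# ---------------------------------------------------------------------------

def drdq_haplotype_analysis(cohort_with_motifs: pd.DataFrame,
                            min_copies: int = 5) -> pd.DataFrame | None:
    """Virtual-reference OR per joint (DRB1 allele, DQ motif) haplotype.

    Requires DRB1 phased with DQ (columns drb1_1/drb1_2).  Haplotypes with
    fewer than ``min_copies`` total copies are excluded.  Returns None with a
    notice when DRB1 is absent.
    """
    if "drb1_1" not in cohort_with_motifs.columns:
        log.info("DRB1 columns absent; DR-DQ haplotype analysis skipped")
        return None
    df = cohort_with_motifs
    frames = []
    for i in (1, 2):
        frames.append(pd.DataFrame({
            "status": df["status"], "drb1": df[f"drb1_{i}"], "motif": df[f"motif_{i}"]}))
    long = pd.concat(frames, ignore_index=True)
    counts = long.groupby(["drb1", "motif", "status"]).size().unstack(fill_value=0)
    for col in (CONTROL, CASE):
        if col not in counts:
            counts[col] = 0
    case_total = int((df["status"] == CASE).sum()) * 2
    control_total = int((df["status"] == CONTROL).sum()) * 2
    rows = []
    for (drb1, motif), r in counts.iterrows():
        if r[CASE] + r[CONTROL] < min_copies:
            continue
        res = virtual_reference_or(r[CASE], case_total, r[CONTROL], control_total,
                                   label=f"{drb1}~{motif}")
        d = res.as_dict()
        d.update({"drb1": drb1, "motif": motif})
        rows.append(d)
    out = pd.DataFrame(rows)
    return out.sort_values(["drb1", "motif"]).reset_index(drop=True) if len(out) else out


def residue_scan(cohort_with_motifs: pd.DataFrame, registry, panel=None,
                 positions=None, min_copies: int = 5) -> pd.DataFrame:
    """Marginal vs motif-adjusted association for every polymorphic residue.

    Each position contributes a multi-level term (one count column per
    non-baseline amino acid), tested by likelihood ratio before and after
    adjusting for the cis-motif design.  Residue variation that the motifs
    already encode should lose significance after adjustment.
    """
    df = cohort_with_motifs
    y = (df["status"] == CASE).astype(float)
    adjust = motif_design(df)
    designs = residue_design(df, registry, positions=positions, panel=panel)
    return conditional_scan(y, adjust, designs, min_copies=min_copies)


def trans_scan(cohort_with_motifs: pd.DataFrame, registry, panel=None,
               min_copies: int = 5) -> pd.DataFrame:
    """Association of each novel trans motif with disease, adjusted for the
    full cis-motif design."""
    df = cohort_with_motifs
    y = (df["status"] == CASE).astype(float)
    adjust = motif_design(df)
    designs = trans_motif_design(df, registry, panel)
    terms = {m: designs[m] for m in designs.columns}
    return conditional_scan(y, adjust, terms, min_copies=min_copies)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (opt-in; the pipeline's default is
    to report unadjusted p-values)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
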