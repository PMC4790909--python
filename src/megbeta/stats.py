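"""Mixed repeated-measures ANOVA with permutation nulls, and behavioral tests.

The factorial designs here have up to three within-subject factors
(network, relevance, 18 time bins) and one two-level between-subject factor
(diagnostic group), optionally with one between-subject covariate (age).
Univariate repeated-measures F statistics are computed through the
orthonormal-contrast (multi-stratum) formulation: each within-subject
effect is represented by orthonormal contrast scores per subject, a
between-subjects GLM is fitted to each score, and sums of squares are
pooled across the effect's contrasts.  For a within effect with q contrasts
in a design with N subjects and p between-subject parameters this yields
the standard df (q, q*(N - p)) — e.g. (17, 357) for the time effect in a
pooled 22-subject design, and (1, 21) for its single-df polynomial
contrasts.

Because samples are small and residual normality is doubtful, p values come
from resampling rather than the F distribution: group labels are re-drawn
without replacement for between-group effects; two-level within-subject
factors are equiprobably swapped per subject; and the time factor uses a
step-change permutation that shuffles the first differences of each series
and re-accumulates them from the series mean, preserving the multiset of
bin-to-bin steps.  No sphericity correction is applied: the permutation
null replaces distributional assumptions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "dprime",
    "independent_t",
    "AnovaResult",
    "rm_anova",
    "perm_null_group",
    "perm_null_condition",
    "perm_null_time",
    "perm_pvalue",
    "PermAnovaResult",
    "permutation_anova",
]

_POLY_NAMES = {1: "linear", 2: "quadratic", 3: "cubic"}


# ---------------------------------------------------------------------------
# behavioral statistics

def dprime(hit_rate: float, fa_rate: float, n_targets: int | None = None,
           n_nontargets: int | None = None, correct: bool = False) -> float:
    """Signal-detection sensitivity: z(hit rate) - z(false-alarm rate).

    Raw rates of exactly 0 or 1 make the normal quantile infinite; with
    ``correct=True`` (and the trial counts supplied) the log-linear
    correction rate -> (rate*N + 0.5) / (N + 1) is applied first.
    """
    h, f = float(hit_rate), float(fa_rate)
    if correct:
        if n_targets is None or n_nontargets is None:
            raise ValueError("correction requires n_targets and n_nontargets")
        h = (h * n_targets + 0.5) / (n_targets + 1)
        f = (f * n_nontargets + 0.5) / (n_nontargets + 1)
    if not (0.0 < h < 1.0 and 0.0 < f < 1.0):
        raise ValueError(
            "rates of exactly 0 or 1 give an infinite quantile; enable the "
            "log-linear correction or supply corrected rates"
        )
    return float(norm.ppf(h) - norm.ppf(f))


def independent_t(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int) -> tuple[float, int]:
    """Pooled-variance independent-samples Student t from summary statistics.

    Returns ``(t, df)`` with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


# ---------------------------------------------------------------------------
# ANOVA core

def _orthonormal_poly(k: int) -> np.ndarray:
    """Orthonormal polynomial contrast basis over k equally spaced levels.

    Column 0 is the constant 1/sqrt(k); column d spans degree-d trend with
    a positive leading coefficient.
    """
    x = np.arange(k, dtype=float)
    V = np.vander(x, k, increasing=True)
    Q, R = np.linalg.qr(V)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


class _Core:
    """Wide-format design: contrast scores, between-design, F computation."""

    def __init__(self, Y: np.ndarray, within: tuple[str, ...],
                 levels: dict[str, list], group_codes: np.ndarray | None,
                 covariate: np.ndarray | None):
        self.within = within
        self.levels = levels
        self.k = [len(levels[f]) for f in within]
        self.Y = np.asarray(Y, dtype=float)
        self.N = self.Y.shape[0]
        C = np.ones((1, 1))
        for kf in self.k:
            C = np.kron(C, _orthonormal_poly(kf))
        self.C = C
        self.degrees = list(itertools.product(*[range(kf) for kf in self.k]))
        self.group_codes = group_codes
        self.covariate = covariate
        self.p = 1 + (group_codes is not None) + (covariate is not None)
        # per-effect column indices: effect key = tuple of factors with deg>0
        self.effect_cols: dict[tuple[str, ...], list[int]] = {}
        for j, d in enumerate(self.degrees):
            key = tuple(f for f, deg in zip(within, d) if deg > 0)
            self.effect_cols.setdefault(key, []).append(j)

    def _X(self, group_codes):
        cols = [np.ones(self.N)]
        names = ["(Intercept)"]
        if group_codes is not None:
            cols.append(group_codes.astype(float))
            names.append("group")
        if self.covariate is not None:
            cols.append(self.covariate - self.covariate.mean())
            names.append("covariate")
        return np.stack(cols, axis=1), names

    def fit(self, Y: np.ndarray | None = None,
            group_codes: np.ndarray | None = None,
            Z: np.ndarray | None = None) -> "AnovaResult":
        if Z is None:
            Y = self.Y if Y is None else Y
            Z = Y @ self.C
        gc = self.group_codes if group_codes is None else group_codes
        X, names = self._X(gc)
        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX)
        B = XtX_inv @ (X.T @ Z)  # (p, J)
        resid = Z - X @ B
        ss_res = np.einsum("ij,ij->j", resid, resid)
        ss_coef = B**2 / np.diag(XtX_inv)[:, None]

        rows = []
        contrasts: dict[str, dict[str, dict]] = {}
        df_err_between = self.N - self.p
        for key, cols in self.effect_cols.items():
            q = len(cols)
            ss_err = float(ss_res[cols].sum())
            df_err = q * df_err_between
            for pi, pname in enumerate(names):
                if key == () and pname == "(Intercept)":
                    ename = "(Intercept)"
                elif key == ():
                    ename = pname
                elif pname == "(Intercept)":
                    ename = ":".join(key)
                else:
                    ename = ":".join(key) + f":{pname}"
                ss = float(ss_coef[pi, cols].sum())
                if ss_err > 0:
                    F = (ss / q) / (ss_err / df_err)
                else:  # zero residual: perfect separation (or no effect at all)
                    F = np.inf if ss > 1e-12 * max(ss_coef.max(), 1.0) else 0.0
                rows.append((ename, q, df_err, ss, F))
        # single-df polynomial contrasts for within factors with >= 3 levels
        for fi, f in enumerate(self.within):
            if self.k[fi] < 3:
                continue
            fc = {}
            for j, d in enumerate(self.degrees):
                deg = d[fi]
                if deg in _POLY_NAMES and all(
                    dd == 0 for ii, dd in enumerate(d) if ii != fi
                ):
                    est = float(B[0, j])
                    if ss_res[j] > 0:
                        F = ss_coef[0, j] / (ss_res[j] / df_err_between)
                    else:
                        F = np.inf if ss_coef[0, j] > 0 else 0.0
                    fc[_POLY_NAMES[deg]] = {
                        "F": float(F), "estimate": est,
                        "sign": int(np.sign(est)),
                        "df": (1, df_err_between),
                    }
            contrasts[f] = fc
        table = pd.DataFrame(rows, columns=["effect", "df_num", "df_den",
                                            "ss", "F"]).set_index("effect")
        return AnovaResult(table=table, contrasts=contrasts, n_subjects=self.N)


@dataclass
class AnovaResult:
    """Effect table (F, dfs) plus single-df polynomial trend contrasts."""

    table: pd.DataFrame
    contrasts: dict[str, dict[str, dict]]
    n_subjects: int

    def F(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def df(self, effect: str) -> tuple[int, int]:
        row = self.table.loc[effect]
        return int(row["df_num"]), int(row["df_den"])


def _build_core(data: pd.DataFrame, dv: str, subject: str,
                within: tuple[str, ...], between: str | None,
                covariate: str | None) -> tuple[_Core, pd.Index]:
    within = tuple(within)
    wide = data.pivot_table(index=subject, columns=list(within), values=dv,
                            aggfunc="mean")
    full = pd.MultiIndex.from_product(
        [sorted(data[c].unique()) for c in within], names=list(within)
    ) if len(within) > 1 else pd.Index(sorted(data[within[0]].unique()),
                                       name=within[0])
    wide = wide.reindex(columns=full)
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete within-subject cells for subjects {bad}")
    levels = {f: sorted(data[f].unique()) for f in within}
    gc = None
    if between is not None:
        per_subj = data.groupby(subject)[between].nunique()
        if (per_subj > 1).any():
            raise ValueError("a subject appears in more than one group")
        glabels = data.groupby(subject)[between].first().reindex(wide.index)
        glevels = sorted(glabels.unique())
        if len(glevels) != 2:
            raise ValueError("the between-subject factor must have 2 levels")
        gc = np.where(glabels.to_numpy() == glevels[0], 1.0, -1.0)
    cov = None
    if covariate is not None:
        cov = data.groupby(subject)[covariate].first().reindex(wide.index)
        cov = cov.to_numpy(dtype=float)
    core = _Core(wide.to_numpy(), within, levels, gc, cov)
    return core, wide.index


def rm_anova(data: pd.DataFrame, dv: str = "value", subject: str = "subject",
             within: tuple[str, ...] = ("relevance",),
             between: str | None = "group",
             covariate: str | None = None) -> AnovaResult:
    """Univariate mixed repeated-measures ANOVA on a long-format table.

    Requires a balanced, complete within-subject crossing (missing cells
    raise, naming the offending subjects).  Unbalanced group sizes are
    handled with effect coding and coefficient (Type III) sums of squares.
    Effects are named ``"factor"``, ``"factor1:factor2"``, with ``group``
    appended for interactions with the between factor; the grand-mean test
    is ``"(Intercept)"``.  Polynomial trend contrasts (linear/quadratic/
    cubic, df = 1, N - p) are reported for every within factor with at
    least three levels.
    """
    core, _ = _build_core(data, dv, subject, tuple(within), between, covariate)
    return core.fit()


# ---------------------------------------------------------------------------
# permutation schemes

def perm_null_group(dataset: pd.DataFrame, rng: np.random.Generator,
                    subject: str = "subject", group: str = "group"
                    ) -> pd.DataFrame:
    """Re-draw group labels over subjects without replacement.

    Group sizes are preserved; all of a subject's rows move together.
    """
    subjects = dataset[subject].unique()
    labels = dataset.groupby(subject)[group].first().loc[subjects].to_numpy()
    permuted = labels[rng.permutation(labels.size)]
    mapping = dict(zip(subjects, permuted))
    out = dataset.copy()
    out[group] = out[subject].map(mapping)
    return out


def perm_null_condition(dataset: pd.DataFrame, rng: np.random.Generator,
                        factor: str = "relevance", subject: str = "subject"
                        ) -> pd.DataFrame:
    """Per subject, equiprobably swap or retain the two condition labels."""
    lv = sorted(dataset[factor].unique())
    if len(lv) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels")
    subjects = dataset[subject].unique()
    flip = dict(zip(subjects, rng.random(subjects.size) < 0.5))
    swap = {lv[0]: lv[1], lv[1]: lv[0]}
    out = dataset.copy()
    do = out[subject].map(flip)
    out.loc[do, factor] = out.loc[do, factor].map(swap)
    return out


def perm_null_time(series: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Step-change permutation of a binned time series.

    The null series starts at the mean of the original series and then adds
    the original first differences in a random order (drawn without
    replacement), preserving the multiset of bin-to-bin steps.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 bins")
    steps = rng.permutation(np.diff(x))
    out = np.empty_like(x)
    out[0] = x.mean()
    out[1:] = out[0] + np.cumsum(steps)
    return out


def _perm_null_time_block(block: np.ndarray, rng: np.random.Generator
                          ) -> np.ndarray:
    """Vectorized step-change permutation along the last axis."""
    d = np.diff(block, axis=-1)
    d = rng.permuted(d, axis=-1)
    out = np.empty_like(block)
    out[..., 0] = block.mean(axis=-1)
    out[..., 1:] = out[..., [0]] + np.cumsum(d, axis=-1)
    return out


def perm_pvalue(observed_F: float, null_Fs: np.ndarray,
                add_one: bool = False) -> float:
    """Frequency of null F values >= the observed F.

    Ties count as extreme (conservative).  ``add_one`` applies the
    (b + 1)/(N + 1) smoothing so p can never be exactly zero.
    """
    nulls = np.asarray(null_Fs, dtype=float)
    if nulls.size < 1:
        raise ValueError("need at least one null value")
    b = int(np.sum(nulls >= observed_F))
    if add_one:
        return (b + 1) / (nulls.size + 1)
    return b / nulls.size


# ---------------------------------------------------------------------------
# permutation ANOVA driver

@dataclass
class PermAnovaResult:
    """Observed ANOVA plus permutation p values per requested effect."""

    observed: AnovaResult
    p_perm: dict[str, float]
    null_F: dict[str, np.ndarray] = field(repr=False)
    contrast_p: dict[str, dict[str, float]] = field(default_factory=dict)
    n_iter: int = 0
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        tab = self.observed.table.copy()
        tab["p_perm"] = pd.Series(self.p_perm)
        return tab


def _scheme_for_effect(effect: str, within, levels, between) -> tuple[str, str]:
    """Pick the resampling scheme matching an effect's null hypothesis.

    Effects involving the between factor permute group labels; within-only
    effects flip their first two-level factor; a pure multi-level (time)
    effect uses the step-change permutation.
    """
    parts = effect.replace(":covariate", "").split(":")
    if effect == "(Intercept)":
        return ("group", "") if between else ("none", "")
    if between and ("group" in parts or effect in ("group", "covariate")):
        return "group", ""
    for f in within:
        if f in parts and len(levels[f]) == 2:
            return "flip", f
    for f in within:
        if f in parts and len(levels[f]) >= 3:
            return "step", f
    raise ValueError(f"no permutation scheme for effect {effect!r}")


def permutation_anova(
    data: pd.DataFrame,
    effects: list[str] | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    dv: str = "value",
    subject: str = "subject",
    within: tuple[str, ...] = ("relevance",),
    between: str | None = "group",
    covariate: str | None = None,
    add_one: bool = False,
    contrast_factor: str | None = None,
) -> PermAnovaResult:
    """Permutation p values for mixed repeated-measures ANOVA effects.

    For each requested effect the observed F is compared with its null
    distribution over ``n_iter`` resamples under the scheme matching that
    effect (group relabeling, per-subject condition flip, or step-change
    time permutation applied per subject-and-condition series).  If
    ``contrast_factor`` is given, permutation p values for its quadratic
    and cubic trend contrasts are computed under the step-change null.
    """
    within = tuple(within)
    core, _ = _build_core(data, dv, subject, within, between, covariate)
    observed = core.fit()
    if effects is None:
        effects = [e for e in observed.table.index if e != "(Intercept)"]
    rng = np.random.default_rng(seed)

    # group effects by scheme so one resample serves all effects under it
    by_scheme: dict[tuple[str, str], list[str]] = {}
    for e in effects:
        if e not in observed.table.index:
            raise KeyError(f"unknown effect {e!r}")
        sch = _scheme_for_effect(e, within, core.levels, between)
        if sch[0] == "none":
            raise ValueError(f"effect {e!r} has no exchangeability scheme")
        by_scheme.setdefault(sch, []).append(e)

    contrast_terms = ("quadratic", "cubic")
    want_contrasts = contrast_factor is not None
    if want_contrasts:
        by_scheme.setdefault(("step", contrast_factor), [])

    null_F: dict[str, list[float]] = {e: [] for e in effects}
    null_contrast = {t: [] for t in contrast_terms} if want_contrasts else {}

    for (kind, factor), eff_list in by_scheme.items():
        if kind == "group":
            gc = core.group_codes.copy()
            for _ in range(n_iter):
                res = core.fit(group_codes=gc[rng.permutation(core.N)])
                for e in eff_list:
                    null_F[e].append(res.F(e))
        elif kind == "flip":
            fi = within.index(factor)
            odd = np.array([d[fi] % 2 == 1 for d in core.degrees])
            Z_signs_base = np.ones((core.N, core.C.shape[1]))
            Ybase = core.Y
            for _ in range(n_iter):
                flips = rng.random(core.N) < 0.5
                S = Z_signs_base.copy()
                S[np.ix_(flips, odd)] = -1.0
                # flipping a 2-level factor negates its odd contrast scores
                Z = (Ybase @ core.C) * S
                res = core.fit(Z=Z)
                for e in eff_list:
                    null_F[e].append(res.F(e))
        elif kind == "step":
            fi = within.index(factor)
            kf = core.k[fi]
            J = core.C.shape[0]
            # gather cell columns into (..., n_other, k_f) blocks
            idx = np.arange(J).reshape(core.k)
            idx = np.moveaxis(idx, fi, -1).reshape(-1, kf)
            for _ in range(n_iter):
                Y = core.Y.copy()
                block = Y[:, idx]  # (N, n_other, k_f)
                Y[:, idx] = _perm_null_time_block(block, rng)
                res = core.fit(Y=Y)
                for e in eff_list:
                    null_F[e].append(res.F(e))
                if want_contrasts and factor == contrast_factor:
                    for t in contrast_terms:
                        null_contrast[t].append(
                            res.contrasts[contrast_factor][t]["F"]
                        )

    p_perm = {e: perm_pvalue(observed.F(e), np.asarray(null_F[e]), add_one)
              for e in effects}
    contrast_p: dict[str, dict[str, float]] = {}
    if want_contrasts:
        contrast_p[contrast_factor] = {
            t: perm_pvalue(
                observed.contrasts[contrast_factor][t]["F"],
                np.asarray(null_contrast[t]), add_one,
            )
            for t in contrast_terms
        }
    return PermAnovaResult(
        observed=observed, p_perm=p_perm,
        null_F={e: np.asarray(v) for e, v in null_F.items()},
        contrast_p=contrast_p, n_iter=n_iter, seed=seed,
    )
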