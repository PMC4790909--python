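"""Integrative-beta x visual-gamma amplitude coupling.

If the late-rising "integrative" beta component in the insula reflects
long-range coordination, its fitted time-course should co-vary with local
gamma-band activity in a remote sensory network engaged by the task.  For
each subject and condition, the predicted integrative beta series (the
fitted integrative Weibull component alone) is correlated with the visual
network's gamma-band envelope at each gamma band over the 900 post-stimulus
samples; Pearson r is Fisher-transformed (z = atanh r) and the z values
enter a mixed ANOVA (relevance x gamma band within subjects, diagnostic
group between).  The grand-mean ("(Intercept)") test asks whether coupling
is positive overall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "CouplingRecord",
    "beta_gamma_correlation",
    "coupling_anova",
    "cross_specificity_check",
]

#: |r| = 1 is mapped to this bound so Fisher z stays finite for the ANOVA.
_R_BOUND = 1.0 - 1e-12


@dataclass(frozen=True)
class CouplingRecord:
    """Correlation between one subject's integrative beta and one gamma band."""

    subject: str
    group: str
    condition: str
    band_center_hz: float
    r: float
    z: float
    flags: tuple[str, ...] = ()


def beta_gamma_correlation(
    predicted_beta: np.ndarray,
    gamma_envelopes: np.ndarray,
    band_centers_hz,
    subject: str = "",
    group: str = "",
    condition: str = "",
) -> list[CouplingRecord]:
    """Pearson r (and Fisher z) per gamma band over the paired samples.

    A constant gamma band yields a record flagged ``undefined`` with NaN
    values (excluded from the ANOVA); |r| = 1 is clamped just inside the
    open interval and flagged ``boundary`` so z stays finite.
    """
    beta = np.asarray(predicted_beta, dtype=float)
    gammas = np.atleast_2d(np.asarray(gamma_envelopes, dtype=float))
    centers = np.asarray(band_centers_hz, dtype=float)
    if gammas.shape[1] != beta.size:
        raise ValueError("beta and gamma series must have equal length")
    if gammas.shape[0] != centers.size:
        raise ValueError("one band center per gamma row is required")
    if beta.std() == 0:
        raise ValueError("constant predicted beta series: correlation undefined")
    bc = beta - beta.mean()
    bnorm = np.linalg.norm(bc)
    records = []
    for g, c in zip(gammas, centers):
        flags: tuple[str, ...] = ()
        gc = g - g.mean()
        gnorm = np.linalg.norm(gc)
        if gnorm == 0:
            records.append(CouplingRecord(subject, group, condition, float(c),
                                          np.nan, np.nan, ("undefined",)))
            continue
        r = float(bc @ gc / (bnorm * gnorm))
        r = min(max(r, -1.0), 1.0)
        if abs(r) >= _R_BOUND:
            r = np.sign(r) * _R_BOUND
            flags = ("boundary",)
        records.append(CouplingRecord(subject, group, condition, float(c),
                                      r, float(np.arctanh(r)), flags))
    return records


def records_frame(records) -> pd.DataFrame:
    rows = [
        dict(subject=r.subject, group=r.group, condition=r.condition,
             band_center_hz=r.band_center_hz, r=r.r, z=r.z,
             flags=";".join(r.flags))
        for r in records
    ]
    return pd.DataFrame(rows)


def coupling_anova(records, n_iter: int = 10_000, seed: int = 0,
                   n_perm_effects: list[str] | None = None
                   ) -> stats.PermAnovaResult:
    """Mixed ANOVA on Fisher-z coupling: relevance x band within, group between.

    Records flagged ``undefined`` (NaN z) are excluded before fitting.  The
    "(Intercept)" effect tests overall positivity of the coupling.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    df = df.dropna(subset=["z"])
    return stats.permutation_anova(
        df, effects=n_perm_effects, n_iter=n_iter, seed=seed, dv="z",
        within=("condition", "band_center_hz"), between="group",
    )


def cross_specificity_check(
    beta_sources: dict[str, dict[str, np.ndarray]],
    gamma_targets: dict[str, dict[str, np.ndarray]],
    band_centers_hz,
) -> pd.DataFrame:
    """Mean Fisher z for every (beta source network, gamma target network).

    ``beta_sources[network][subject]`` is a predicted integrative beta
    series; ``gamma_targets[network][subject]`` is a band x time gamma
    envelope array.  Returns a tidy frame with one row per cell: mean z
    across subjects and bands, plus a one-sample F (squared t) for the mean
    z being nonzero across subjects.  Coupling restricted to one
    source-target pair should make that cell the matrix maximum.
    """
    src_names = sorted(beta_sources)
    tgt_names = sorted(gamma_targets)
    if len(src_names) < 2 or len(tgt_names) < 2:
        raise ValueError("need at least 2 networks on each axis")
    rows = []
    for s in src_names:
        for t in tgt_names:
            subj_z = []
            for subj, beta in beta_sources[s].items():
                recs = beta_gamma_correlation(
                    beta, gamma_targets[t][subj], band_centers_hz,
                    subject=subj,
                )
                zs = [r.z for r in recs if np.isfinite(r.z)]
                if zs:
                    subj_z.append(float(np.mean(zs)))
            subj_z = np.asarray(subj_z)
            n = subj_z.size
            mean_z = float(subj_z.mean())
            if n > 1 and subj_z.std(ddof=1) > 0:
                F = n * mean_z**2 / float(subj_z.var(ddof=1))
            else:
                F = np.inf if mean_z != 0 else 0.0
            rows.append(dict(source=s, target=t, mean_z=mean_z, F=float(F),
                             n=n))
    return pd.DataFrame(rows)
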