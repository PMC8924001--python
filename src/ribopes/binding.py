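"""Equilibrium binding-curve fitting and pulldown fold-change quantification.

The fraction of RNA bound at protein concentration C follows the one-site
hyperbola f(C) = C / (Kd + C) (optionally with a Hill exponent), with the
ceiling fixed at 1 because an EMSA fraction bound is already a ratio.  A
curve that does not improve significantly on the best flat (constant) fit is
reported as a no-binding verdict rather than a numeric Kd — the outcome a
scrambled-oligo control produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class BindingFit:
    """Result of a one-site binding fit."""

    kd_um: float | None
    kd_se_um: float | None
    hill: float
    rss: float
    rss_flat: float
    f_statistic: float
    p_vs_flat: float
    verdict: str  # "binding" or "no_binding"
    n_points: int

    def as_dict(self) -> dict:
        return {
            "kd_um": self.kd_um, "kd_se_um": self.kd_se_um, "hill": self.hill,
            "rss": self.rss, "rss_flat": self.rss_flat,
            "f_statistic": self.f_statistic, "p_vs_flat": self.p_vs_flat,
            "verdict": self.verdict, "n_points": self.n_points,
        }


def hyperbola(conc, kd, hill: float = 1.0):
    c = np.asarray(conc, dtype=float)
    return c**hill / (kd**hill + c**hill)


def fit_kd(
    concentrations,
    fraction_bound,
    hill: float = 1.0,
    alpha: float = 0.05,
    n_starts: int = 7,
) -> BindingFit:
    """Least-squares fit of f(C) = C/(Kd + C) with a no-binding verdict.

    Multi-start over log-spaced initial Kd values spanning the concentration
    range; the standard error comes from the Jacobian at the optimum.  The
    fit must beat the best constant model in an extra-sum-of-squares F test
    at level ``alpha``, otherwise the verdict is "no_binding" and no Kd is
    reported.  Replicate measurements may simply be passed as repeated
    (concentration, fraction) pairs.
    """
    c = np.asarray(concentrations, dtype=float).ravel()
    f = np.asarray(fraction_bound, dtype=float).ravel()
    if c.shape != f.shape:
        raise ValueError("concentration and fraction arrays differ in length")
    ok = np.isfinite(c) & np.isfinite(f)
    c, f = c[ok], f[ok]
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    n = c.size

    rss_flat = float(np.sum((f - f.mean()) ** 2))

    best = None
    for kd0 in np.geomspace(c.min() / 10, c.max() * 10, n_starts):
        try:
            popt, pcov = optimize.curve_fit(
                lambda x, kd: hyperbola(x, kd, hill), c, f,
                p0=[kd0], bounds=(1e-12, np.inf), maxfev=10_000,
                xtol=1e-12, ftol=1e-12,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((f - hyperbola(c, popt[0], hill)) ** 2))
        if best is None or rss < best[2]:
            best = (float(popt[0]), pcov, rss)
    if best is None:
        return BindingFit(None, None, hill, math.inf, rss_flat, 0.0, 1.0,
                          "no_binding", n)
    kd, pcov, rss = best
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else None

    # extra-sum-of-squares F test against the best constant fit
    df_denom = max(n - 2, 1)
    if rss <= 0:
        f_stat, p = math.inf, 0.0
    elif rss >= rss_flat:
        f_stat, p = 0.0, 1.0
    else:
        f_stat = (rss_flat - rss) / (rss / df_denom)
        p = float(stats.f.sf(f_stat, 1, df_denom))
    verdict = "binding" if p < alpha else "no_binding"
    return BindingFit(
        kd_um=kd if verdict == "binding" else None,
        kd_se_um=se if verdict == "binding" else None,
        hill=hill, rss=rss, rss_flat=rss_flat,
        f_statistic=f_stat, p_vs_flat=p, verdict=verdict, n_points=n,
    )


def pulldown_log2fc(signal: float, baseline: float,
                    floor: float | None = None) -> dict:
    """log2 fold change of a co-precipitated fraction over its no-RNA baseline.

    A zero signal is only admissible with an explicit detection floor, in
    which case the floored value is used and flagged.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    flagged = False
    if signal <= 0:
        if floor is None:
            raise ValueError("non-positive signal requires a detection floor")
        signal = floor
        flagged = True
    return {"log2fc": math.log2(signal / baseline), "floored": flagged}
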