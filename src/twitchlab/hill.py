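"""Hill-equation analysis of steady-state tension vs pCa.

The force-pCa relation of permeabilized cardiac muscle is summarized by

    T_SS(pCa) = T_SS,Max * [1 + 10^(n_H * (pCa - pCa50))]^-1

where ``T_SS,Max`` is the tension at saturating Ca2+, ``pCa50`` the pCa at
half-maximal tension (Ca2+ sensitivity) and ``n_H`` the Hill coefficient
(cooperativity); tension falls as pCa rises (i.e. as Ca2+ falls).  The module follows the statsmodels convention: build a
:class:`HillCurve` model from data, call :meth:`HillCurve.fit`, and read
estimates, uncertainties and a ``summary()`` table off the returned
:class:`HillCurveResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "HillFit",
    "HillCurve",
    "HillCurveResults",
    "hill_predict",
    "fit_hill",
    "fit_dataset",
    "compare_groups",
]

PCA_RANGE = (3.5, 9.5)
#: pCa defining the saturating reference point for normalization
PCA_SATURATING = 4.0


@dataclass(frozen=True)
class HillFit:
    """Point estimates of the Hill parameters with fit diagnostics."""

    T_SS_Max: float
    pCa50: float
    n_H: float
    residual_sse: float = np.nan
    converged: bool = True

    def __post_init__(self):
        if not self.n_H > 0:
            raise ValueError("Hill coefficient must be positive")


def hill_predict(pCa, fit: HillFit):
    """Steady-state tension at the given pCa under a fitted Hill model."""
    pCa = np.asarray(pCa, dtype=float)
    out = fit.T_SS_Max / (1.0 + 10.0 ** (fit.n_H * (pCa - fit.pCa50)))
    return float(out) if out.ndim == 0 else out


def _validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    required = {"prep_id", "genotype", "pCa", "tension"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing columns {sorted(missing)}")
    if ((df["pCa"] < PCA_RANGE[0]) | (df["pCa"] > PCA_RANGE[1])).any():
        raise ValueError(f"pCa values outside {PCA_RANGE}")
    if (df["tension"] < 0).any():
        raise ValueError("negative tensions in dataset")
    return df


class HillCurve:
    """Hill model for one tension-pCa curve.

    Parameters
    ----------
    tension, pCa : array-like
        Paired observations for a single preparation.
    normalize : bool
        Express tensions as percent of the value at the saturating point
        (pCa 4.0, or the maximum observed if 4.0 was not sampled).
    """

    def __init__(self, tension, pCa, normalize: bool = False):
        self.pCa = np.asarray(pCa, dtype=float)
        self.tension = np.asarray(tension, dtype=float)
        if self.pCa.shape != self.tension.shape or self.pCa.ndim != 1:
            raise ValueError("tension and pCa must be 1-D and equal length")
        if np.unique(self.pCa).size < 4:
            raise ValueError("need >= 4 distinct pCa levels to fit 3 parameters")
        if not np.any(self.tension > 0):
            raise ValueError("all tensions are zero; degenerate dataset")
        if normalize:
            at_sat = self.tension[np.isclose(self.pCa, PCA_SATURATING, atol=0.05)]
            if at_sat.size:
                ref = float(np.mean(at_sat))
            else:
                warnings.warn(
                    "no sample at the saturating pCa 4.0; normalizing to the "
                    "maximum observed tension",
                    UserWarning,
                    stacklevel=2,
                )
                ref = float(np.max(self.tension))
            self.tension = 100.0 * self.tension / ref
        self.normalized = normalize

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, prep_id=None,
                       normalize: bool = False) -> "HillCurve":
        """Build the model for one preparation of a long-format dataset."""
        df = _validate_dataset(df)
        if prep_id is not None:
            df = df[df["prep_id"] == prep_id]
            if df.empty:
                raise KeyError(f"no rows for preparation {prep_id!r}")
        return cls(df["tension"].to_numpy(), df["pCa"].to_numpy(),
                   normalize=normalize)

    def fit(self) -> "HillCurveResults":
        """Nonlinear least squares with multi-start on the Hill coefficient."""
        T, pCa = self.tension, self.pCa
        T_max0 = float(np.max(T))
        # pCa of the sample closest to half-max seeds the sensitivity
        pca50_0 = float(pCa[np.argmin(np.abs(T - T_max0 / 2.0))])

        best = None
        for n0 in (2.0, 1.0, 4.0):
            try:
                popt, pcov = optimize.curve_fit(
                    lambda x, tmax, p50, nh: tmax / (1 + 10 ** (nh * (x - p50))),
                    pCa, T, p0=(T_max0, pca50_0, n0),
                    bounds=((0.0, PCA_RANGE[0], 1e-3), (np.inf, PCA_RANGE[1], 20.0)),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            resid = T - popt[0] / (1 + 10 ** (popt[2] * (pCa - popt[1])))
            sse = float(resid @ resid)
            if best is None or sse < best[2]:
                best = (popt, pcov, sse)
        if best is None:
            raise RuntimeError(
                "Hill fit failed to converge from all starting points "
                f"(n={T.size}, pCa range {pCa.min():.2f}-{pCa.max():.2f})"
            )
        popt, pcov, sse = best
        if not (pCa.min() - 1e-9 <= popt[1] <= pCa.max() + 1e-9):
            raise RuntimeError(
                f"fitted pCa50 {popt[1]:.3f} lies outside the sampled pCa "
                f"range [{pCa.min():.2f}, {pCa.max():.2f}]; refusing to "
                "extrapolate"
            )
        fit = HillFit(T_SS_Max=float(popt[0]), pCa50=float(popt[1]),
                      n_H=float(popt[2]), residual_sse=sse, converged=True)
        return HillCurveResults(self, fit, pcov)


class HillCurveResults:
    """Fitted Hill curve: estimates, standard errors, prediction, summary."""

    param_names = ("T_SS_Max", "pCa50", "n_H")

    def __init__(self, model: HillCurve, fit: HillFit, cov: np.ndarray):
        self.model = model
        self.fit = fit
        self.cov_params = np.asarray(cov)
        self.params = np.array([fit.T_SS_Max, fit.pCa50, fit.n_H])
        with np.errstate(invalid="ignore"):
            self.bse = np.sqrt(np.diag(self.cov_params))

    @property
    def nobs(self) -> int:
        return self.model.tension.size

    def predict(self, pCa):
        return hill_predict(pCa, self.fit)

    def summary(self) -> str:
        lines = [
            "Hill tension-pCa fit",
            "=" * 44,
            f"{'n obs':<14}{self.nobs:>10}",
            f"{'residual SSE':<14}{self.fit.residual_sse:>10.4g}",
            "-" * 44,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<12}{est:>12.4f}{se:>12.4f}")
        lines.append("=" * 44)
        return "\n".join(lines)


def fit_hill(tension, pCa, normalize: bool = False) -> HillFit:
    """Functional front end: fit one curve, return the :class:`HillFit`."""
    return HillCurve(tension, pCa, normalize=normalize).fit().fit


def fit_dataset(df: pd.DataFrame, normalize: bool = False) -> pd.DataFrame:
    """Fit every preparation of a long-format dataset.

    Returns a tidy frame with one row per preparation: genotype, the three
    Hill parameters, residual SSE and convergence flag.
    """
    df = _validate_dataset(df)
    rows = []
    for (prep, geno), sub in df.groupby(["prep_id", "genotype"], sort=False):
        res = HillCurve(sub["tension"].to_numpy(), sub["pCa"].to_numpy(),
                        normalize=normalize).fit()
        rows.append({
            "prep_id": prep, "genotype": geno,
            "T_SS_Max": res.fit.T_SS_Max, "pCa50": res.fit.pCa50,
            "n_H": res.fit.n_H, "residual_sse": res.fit.residual_sse,
            "converged": res.fit.converged,
        })
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    field: str
    anova_F: float
    anova_p: float
    group_means: pd.DataFrame
    tukey: pd.DataFrame
    meta: dict = field(default_factory=dict)


def compare_groups(fits: pd.DataFrame, field: str = "pCa50") -> GroupComparison:
    """One-way ANOVA plus Tukey HSD on a per-preparation fit table.

    ``fits`` is the output of :func:`fit_dataset` (columns ``genotype`` and
    the requested field).  Every group needs >= 2 preparations.
    """
    if field not in ("pCa50", "n_H", "T_SS_Max"):
        raise ValueError("field must be one of pCa50, n_H, T_SS_Max")
    groups = {g: sub[field].to_numpy() for g, sub in fits.groupby("genotype")}
    if len(groups) < 2:
        raise ValueError("need at least 2 genotype groups")
    small = [g for g, v in groups.items() if v.size < 2]
    if small:
        raise ValueError(f"groups with < 2 preparations: {small}")
    if np.ptp(fits[field].to_numpy()) == 0:
        # all observations identical: no effect and no noise
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*groups.values())
    means = fits.groupby("genotype")[field].agg(["mean", "std", "count"])
    if np.ptp(fits[field].to_numpy()) == 0:
        names = sorted(groups)
        tukey = pd.DataFrame(
            [(a, b, 0.0, 1.0, False) for i, a in enumerate(names)
             for b in names[i + 1:]],
            columns=["group1", "group2", "meandiff", "p-adj", "reject"],
        )
    else:
        tukey_res = pairwise_tukeyhsd(fits[field].to_numpy(),
                                      fits["genotype"].to_numpy())
        tukey = pd.DataFrame(tukey_res.summary().data[1:],
                             columns=tukey_res.summary().data[0])
    return GroupComparison(field=field, anova_F=float(F), anova_p=float(p),
                           group_means=means, tukey=tukey)
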