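"""Blood permeability assay: fluorescence calibration and group statistics.

Plate-reader fluorescence of hemolysed whole blood (10 uL blood + 20 uL EDTA,
a 3x dilution) is converted to tracer concentration through a linear standard
curve; samples below the limit of detection (blank mean + 3 SD, a standard
analytical convention) are censored.  Group contrasts use one-way ANOVA with
Tukey's HSD (Tukey-Kramer for unequal n), the design the permeability figures
report, plus percent-reduction and fold-change summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StandardCurve",
    "GroupComparison",
    "fit_standard_curve",
    "to_concentration",
    "percent_reduction",
    "fold_change",
    "anova_oneway",
    "group_compare",
]

DEFAULT_DILUTION = 3.0  # 10 uL blood into 30 uL total


class AssayError(ValueError):
    """Invalid calibration or comparison input."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear fluorescence-vs-concentration calibration with detection limit.

    ``F = intercept + slope * C``; LOD is in concentration units (ng/ml).
    """

    slope: float
    intercept: float
    lod: float
    r_squared: float = float("nan")
    residual_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise AssayError(f"standard curve slope must be > 0, got {self.slope}")
        if self.lod < 0:
            raise AssayError("LOD must be >= 0")

    def predict(self, conc: float | np.ndarray) -> np.ndarray:
        """Fluorescence expected for a given concentration."""
        return self.intercept + self.slope * np.asarray(conc, float)


def fit_standard_curve(
    concentrations: np.ndarray, fluorescences: np.ndarray, blanks: np.ndarray
) -> StandardCurve:
    """Ordinary least-squares line through calibration standards.

    ``concentrations`` and ``fluorescences`` are flat, paired arrays (use
    repeated concentration values for replicates).  LOD = (blank SD * 3)
    expressed as concentration through the slope, relative to the blank mean
    which serves as the effective intercept check.
    """
    conc = np.asarray(concentrations, float)
    fluo = np.asarray(fluorescences, float)
    blank = np.asarray(blanks, float)
    if np.unique(conc).size < 4:
        raise AssayError("need >= 4 distinct concentration levels")
    if conc.size != fluo.size:
        raise AssayError("concentrations and fluorescences must be paired")
    if blank.size < 1:
        raise AssayError("need at least one blank well")

    X = np.column_stack([np.ones_like(conc), conc])
    (intercept, slope), res, *_ = np.linalg.lstsq(X, fluo, rcond=None)
    if slope <= 0:
        raise AssayError("non-monotone calibration: fitted slope <= 0")

    fitted = X @ np.array([intercept, slope])
    ss_res = float(np.sum((fluo - fitted) ** 2))
    ss_tot = float(np.sum((fluo - fluo.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(conc.size - 2, 1)
    resid_sd = float(np.sqrt(ss_res / dof))

    blank_sd = float(np.std(blank, ddof=1)) if blank.size > 1 else 0.0
    blank_mean = float(blank.mean())
    # LOD rule: blank mean + 3 SD, expressed as concentration through the line
    lod = max((blank_mean + 3.0 * blank_sd - intercept) / slope, 0.0)
    return StandardCurve(slope=float(slope), intercept=float(intercept),
                         lod=lod, r_squared=r2, residual_sd=resid_sd)


def to_concentration(
    curve: StandardCurve, fluorescence: float, dilution: float = DEFAULT_DILUTION
) -> tuple[float, bool]:
    """Invert the standard curve for one sample.

    Returns (concentration ng/ml in the original blood, censored flag).
    The measured (diluted) concentration is compared against the LOD; the
    returned value is scaled back up by the dilution factor and floored at 0.
    """
    if dilution < 1:
        raise AssayError("dilution factor must be >= 1")
    measured = (fluorescence - curve.intercept) / curve.slope
    censored = measured < curve.lod
    return max(measured, 0.0) * dilution, bool(censored)


def percent_reduction(control_mean: float, treated_mean: float) -> dict:
    """(1 - treated/control) * 100, clipped to [0, 100].

    A treated mean above control is reported as 0% with ``increased=True``.
    """
    if control_mean <= 0:
        raise AssayError("control mean must be > 0")
    raw = (1.0 - treated_mean / control_mean) * 100.0
    return {"percent": max(raw, 0.0), "increased": raw < 0}


def fold_change(
    numerator_mean: float, denominator_mean: float, lod: float | None = None
) -> dict:
    """Ratio of group means; a censored denominator is substituted by LOD/2."""
    flagged = False
    if denominator_mean <= 0:
        if lod is not None and lod > 0:
            denominator_mean = lod / 2.0
            flagged = True
        else:
            raise AssayError("denominator mean must be > 0 (or provide an LOD)")
    return {"fold": numerator_mean / denominator_mean, "censored_denominator": flagged}


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise contrasts."""

    groups: list
    means: np.ndarray
    sems: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame | None = field(default=None)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.groups, "n": self.ns, "mean": self.means,
             "sd": self.sds, "sem": self.sems}
        )


def anova_oneway(samples: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p value across labelled groups."""
    arrays = [np.asarray(v, float) for v in samples.values()]
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def group_compare(
    samples: dict[str, np.ndarray], tukey: bool = True, alpha: float = 0.05
) -> GroupComparison:
    """Group means +/- SEM, one-way ANOVA, and Tukey-adjusted pairwise p values."""
    if len(samples) < 2:
        raise AssayError("need >= 2 groups")
    for g, v in samples.items():
        if np.asarray(v).size < 2:
            raise AssayError(f"group {g!r} needs n >= 2")

    groups = list(samples)
    arrays = [np.asarray(samples[g], float) for g in groups]
    means = np.array([a.mean() for a in arrays])
    sds = np.array([a.std(ddof=1) for a in arrays])
    ns = np.array([a.size for a in arrays])
    sems = sds / np.sqrt(ns)

    if all(np.allclose(a, arrays[0][0]) for a in arrays):
        f, p = 0.0, 1.0
    else:
        f, p = anova_oneway(samples)

    tukey_df = None
    if tukey:
        values = np.concatenate(arrays)
        labels = np.concatenate([[g] * n for g, n in zip(groups, ns)])
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        tukey_df = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        tukey_df["p-adj"] = np.asarray(res.pvalues, float)

    return GroupComparison(groups=groups, means=means, sems=sems, sds=sds,
                           ns=ns, f_statistic=f, p_value=p, tukey=tukey_df)


def read_plate_csv(path) -> pd.DataFrame:
    """Read a plate layout CSV: well, type {standard, blank, sample},
    known_conc_ng_ml, fluorescence, animal_id, group."""
    df = pd.read_csv(path)
    required = {"well", "type", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise AssayError(f"plate CSV missing columns: {sorted(missing)}")
    return df


def process_plate(
    plate: pd.DataFrame, dilution: float = DEFAULT_DILUTION
) -> tuple[StandardCurve, pd.DataFrame]:
    """Fit the calibration from a plate table and convert all sample wells.

    Returns the fitted curve and a per-sample table with derived
    concentrations and censoring flags.
    """
    std = plate[plate["type"] == "standard"]
    blank = plate[plate["type"] == "blank"]
    samp = plate[plate["type"] == "sample"]
    curve = fit_standard_curve(
        std["known_conc_ng_ml"].to_numpy(),
        std["fluorescence"].to_numpy(),
        blank["fluorescence"].to_numpy(),
    )
    rows = []
    for _, r in samp.iterrows():
        conc, cens = to_concentration(curve, r["fluorescence"], dilution)
        rows.append({"animal_id": r.get("animal_id", ""), "group": r.get("group", ""),
                     "conc_ng_ml": conc, "censored": cens})
    return curve, pd.DataFrame(rows)
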