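"""Classify the origin of individual homozygosity: consanguinity vs drift.

Two complementary views are used.  In the (NROH, SROH) plane, drift moves
individuals along the outbred baseline (count and summed length of ROH grow
together), whereas recent consanguinity adds disproportionately long ROH and
shifts individuals to the right of the baseline; the shift is compared with
simulated consanguineous-mating clouds to name the nearest mating class.  In
the (F_ROH, F_IS) plane, individuals near the diagonal F_IS = F_ROH carry a
dominant systematic-inbreeding (consanguinity) component, individuals near
the horizontal F_IS = 0 show panmictic inbreeding from drift, and clearly
negative F_IS indicates isolation and small effective population size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree_sim import Envelope

REGIONS = ("consanguineous", "panmictic_drift", "drift_isolation")


@dataclass(frozen=True)
class BaselineFit:
    """OLS line NROH = intercept + slope * SROH fitted on an outbred panel."""

    slope: float
    intercept: float

    def implied_sroh(self, nroh: float) -> float:
        """Baseline SROH at a given NROH (inverse of the regression line)."""
        if self.slope == 0:
            raise ZeroDivisionError("baseline slope is zero; SROH shift undefined")
        return (nroh - self.intercept) / self.slope


@dataclass
class OriginCall:
    sample_id: str
    sroh_shift_mb: float
    nearest_mating_type: str | None
    fis_froh_region: str | None


def fit_outbred_baseline(points: np.ndarray | list[tuple[float, float]]) -> BaselineFit:
    """Fit the outbred reference line by OLS of NROH on SROH.

    ``points`` are (nroh, sroh) pairs from a reference panel without
    consanguinity; at least 3 points with non-zero SROH variance required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (nroh, sroh) points")
    nroh, sroh = pts[:, 0], pts[:, 1]
    if np.var(sroh) == 0:
        raise ValueError("SROH variance is zero; baseline is degenerate")
    res = stats.linregress(sroh, nroh)
    return BaselineFit(slope=float(res.slope), intercept=float(res.intercept))


def _fis_region(f_is: float, f_roh: float, fis_tolerance: float) -> str:
    """Three-region rule on the (F_ROH, F_IS) plane.

    Clearly negative F_IS (below -tolerance) -> drift_isolation; otherwise
    F_IS strictly closer to the diagonal (F_IS = F_ROH) than to the
    horizontal (F_IS = 0) -> consanguineous; ties and the rest ->
    panmictic_drift.
    """
    if f_is < -fis_tolerance:
        return "drift_isolation"
    if abs(f_is - f_roh) < abs(f_is):
        return "consanguineous"
    return "panmictic_drift"


def classify_origin(
    profile,
    baseline: BaselineFit,
    envelopes: dict[str, Envelope] | None = None,
    fis_tolerance: float = 0.01,
) -> OriginCall:
    """Classify one sample's homozygosity origin.

    ``profile`` is an :class:`rohkin.inbreeding.InbreedingProfile` (or any
    object with ``sample_id``, ``nroh``, ``sroh_mb``, ``f_roh``, ``f_is``).
    The SROH shift is observed SROH minus the baseline-implied SROH at the
    sample's NROH.  If simulation envelopes are given and the shift exceeds
    the second-cousin cloud's mean shift, the Mahalanobis-nearest mating
    class is reported.
    """
    shift = profile.sroh_mb - baseline.implied_sroh(profile.nroh)
    nearest: str | None = None
    if envelopes:
        gate = 0.0
        if "second_cousin" in envelopes:
            sc = envelopes["second_cousin"]
            gate = sc.mean[1] - baseline.implied_sroh(sc.mean[0])
        if shift > gate:
            best, best_d = None, np.inf
            x = np.array([profile.nroh, profile.sroh_mb], dtype=float)
            for mtype, env in envelopes.items():
                if mtype == "unrelated":
                    continue
                cov_inv = np.linalg.pinv(env.cov)
                d = float((x - env.mean) @ cov_inv @ (x - env.mean))
                if d < best_d:
                    best, best_d = mtype, d
            nearest = best
    region: str | None = None
    f_is = getattr(profile, "f_is", None)
    if f_is is not None and not (isinstance(f_is, float) and np.isnan(f_is)):
        region = _fis_region(float(f_is), profile.f_roh, fis_tolerance)
    return OriginCall(
        sample_id=profile.sample_id,
        sroh_shift_mb=float(shift),
        nearest_mating_type=nearest,
        fis_froh_region=region,
    )


def classify_cohort(
    profiles: pd.DataFrame,
    baseline: BaselineFit,
    envelopes: dict[str, Envelope] | None = None,
    fis_tolerance: float = 0.01,
) -> pd.DataFrame:
    """Vector version of :func:`classify_origin` over a profiles table."""
    from types import SimpleNamespace

    rows = []
    for r in profiles.itertuples():
        call = classify_origin(
            SimpleNamespace(sample_id=r.sample_id, nroh=r.nroh, sroh_mb=r.sroh_mb,
                            f_roh=r.f_roh, f_is=r.f_is),
            baseline, envelopes, fis_tolerance,
        )
        rows.append(
            {
                "sample_id": call.sample_id,
                "sroh_shift_mb": call.sroh_shift_mb,
                "nearest_mating_type": call.nearest_mating_type or "none",
                "fis_froh_region": call.fis_froh_region or "unknown",
            }
        )
    return pd.DataFrame(rows)


def group_anova(values, groups) -> tuple[float, float]:
    """One-way ANOVA of ``values`` across ``groups`` (labels per sample).

    Returns (F statistic, p-value).  Requires at least two groups with two
    or more samples each and some within- or between-group variance.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    samples = [values[groups == glab] for glab in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs >= 2 samples")
    if all(np.var(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        raise ValueError("all values identical; ANOVA undefined")
    f, p = stats.f_oneway(*samples)
    # identical group means with positive within-group variance -> F = 0, p = 1
    return float(f), float(p)
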