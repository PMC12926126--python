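"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival figures are often the only patient-level evidence
available to a modeller.  This module inverts a digitized Kaplan-Meier
curve together with its numbers-at-risk table back into per-subject
(time, event) records, interval by interval, so that the product-limit
estimator of the reconstruction reproduces the digitized curve.  The
inversion is fully deterministic: censoring times are spread evenly
within each inter-risk-time interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

logger = logging.getLogger(__name__)

#: survival increases up to this size are treated as digitization jitter
#: and clamped to the running minimum; anything larger is an input error.
JITTER_TOL = 1e-6

DAYS_PER_MONTH = 365.25 / 12.0


class CurveValidationError(ValueError):
    """Digitized-curve input violates a structural invariant."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized KM coordinates plus the at-risk table for one arm/endpoint.

    Parameters
    ----------
    endpoint : str
        Endpoint label, ``"PFS"`` or ``"OS"``.
    arm : str
        Arm label (free text, e.g. ``"treatment"``).
    points : sequence of (float, float)
        Ordered ``(time_months, survival)`` clicks; the first must be
        ``(0, 1)`` and survival must be non-increasing.
    risk_table : sequence of (float, int)
        Ordered ``(time_months, n_at_risk)`` rows with non-increasing
        counts.
    total_events : int, optional
        Reported total event count, used to rescale the final interval
        when supplied.
    """

    endpoint: str
    arm: str
    points: tuple[tuple[float, float], ...]
    risk_table: tuple[tuple[float, int], ...]
    total_events: int | None = None

    def __post_init__(self) -> None:
        pts = [(float(t), float(s)) for t, s in self.points]
        if not pts:
            raise CurveValidationError("curve has no points")
        if not (pts[0][0] == 0.0 and abs(pts[0][1] - 1.0) < 1e-12):
            raise CurveValidationError(
                f"first point must be (0, 1.0), got {pts[0]}"
            )
        times = [t for t, _ in pts]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise CurveValidationError("point times must be strictly increasing")
        cleaned = []
        running = 1.0
        for i, (t, s) in enumerate(pts):
            if s > running + JITTER_TOL:
                raise CurveValidationError(
                    f"survival increases at row {i} (t={t}, S={s} > {running})"
                )
            s = min(s, running)
            if not (0.0 <= s <= 1.0):
                raise CurveValidationError(f"survival out of [0,1] at row {i}")
            running = s
            cleaned.append((t, s))
        object.__setattr__(self, "points", tuple(cleaned))

        risk = [(float(t), int(n)) for t, n in self.risk_table]
        if not risk:
            raise CurveValidationError("risk table is empty")
        rtimes = [t for t, _ in risk]
        if any(b <= a for a, b in zip(rtimes, rtimes[1:])):
            raise CurveValidationError("risk-table times must be strictly increasing")
        counts = [n for _, n in risk]
        if any(n < 0 for n in counts):
            raise CurveValidationError("at-risk counts must be non-negative")
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise CurveValidationError("at-risk counts must be non-increasing")
        object.__setattr__(self, "risk_table", tuple(risk))
        if self.total_events is not None and self.total_events < 0:
            raise CurveValidationError("total_events must be non-negative")

    def survival_at_clicks(self) -> np.ndarray:
        return np.array([s for _, s in self.points])

    def click_times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed per-subject records for one arm/endpoint.

    ``records`` holds ``(time_months, event)`` pairs with ``event`` 1 for
    an observed event and 0 for censoring.
    """

    records: tuple[tuple[float, int], ...]
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("PseudoIPD must contain at least one record")
        recs = tuple((float(t), int(d)) for t, d in self.records)
        for t, d in recs:
            if not (t > 0 and math.isfinite(t)):
                raise ValueError(f"record time must be positive and finite, got {t}")
            if d not in (0, 1):
                raise ValueError(f"event indicator must be 0/1, got {d}")
        object.__setattr__(self, "records", recs)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.records])

    @property
    def events(self) -> np.ndarray:
        return np.array([d for _, d in self.records])

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.times,
                "event": self.events,
                "arm": self.arm,
                "endpoint": self.endpoint,
            }
        )


def read_digitized_curve(
    curve_file: str | Path,
    risk_file: str | Path,
    *,
    endpoint: str = "",
    arm: str = "",
    total_events: int | None = None,
) -> DigitizedCurve:
    """Read ``curve.csv`` (time_months,survival) and ``risk.csv``
    (time_months,n_risk) into a validated :class:`DigitizedCurve`.

    Points are sorted by time; duplicate times keep the last row; a
    missing ``(0, 1)`` anchor is inserted with a warning.
    """
    cdf = pd.read_csv(curve_file)
    rdf = pd.read_csv(risk_file)
    for df, cols, name in ((cdf, ("time_months", "survival"), curve_file),
                           (rdf, ("time_months", "n_risk"), risk_file)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CurveValidationError(f"{name}: missing columns {missing}")
    cdf = cdf.sort_values("time_months", kind="stable").drop_duplicates(
        "time_months", keep="last"
    )
    pts = list(zip(cdf["time_months"].tolist(), cdf["survival"].tolist()))
    if not pts or pts[0][0] > 0:
        logger.warning(
            "curve %s lacks a (0, 1.0) anchor; inserting one", curve_file
        )
        pts.insert(0, (0.0, 1.0))
    rdf = rdf.sort_values("time_months", kind="stable").drop_duplicates(
        "time_months", keep="last"
    )
    risk = list(zip(rdf["time_months"].tolist(), rdf["n_risk"].tolist()))
    return DigitizedCurve(
        endpoint=endpoint, arm=arm, points=tuple(pts), risk_table=tuple(risk),
        total_events=total_events,
    )


class ReconstructionError(RuntimeError):
    """Inversion failed for an interval (inconsistent digitized inputs)."""


def reconstruct_ipd(curve: DigitizedCurve) -> PseudoIPD:
    """Invert a digitized KM curve into pseudo individual-patient data.

    For each interval between consecutive at-risk times the number of
    censorings is adjusted iteratively until the reconstructed at-risk
    count at the next published time matches the table; event counts at
    each click follow from the product-limit ratios.  Censoring times are
    spread equally within the interval; after the last published at-risk
    time censoring is assumed administrative (all survivors censored at
    the final click).

    Entirely deterministic: identical inputs give identical output.
    """
    t = curve.click_times()
    S = curve.survival_at_clicks()
    K = len(t)
    rtimes = np.array([rt for rt, _ in curve.risk_table])
    rcounts = np.array([n for _, n in curve.risk_table])
    # at-risk entries beyond the digitized curve carry no information
    keep = rtimes <= t[-1] + 1e-9
    rtimes, rcounts = rtimes[keep], rcounts[keep]
    if len(rtimes) == 0:
        raise ReconstructionError("risk table lies entirely beyond the curve")
    if rcounts[0] <= 0:
        raise ReconstructionError("at-risk count at the first interval is zero")

    # lower[i]: first click index at/after risk time i
    nint = len(rtimes)
    lower = np.searchsorted(t, rtimes, side="left")
    upper = np.empty(nint, dtype=int)
    upper[:-1] = lower[1:] - 1
    upper[-1] = K - 1

    d = np.zeros(K, dtype=int)          # events at click k
    cens_k = np.zeros(K, dtype=int)     # censorings in [t_k, t_{k+1})
    n_hat = np.zeros(K + 1)
    n_hat[lower[0]] = rcounts[0]
    km = np.ones(K)

    def _propagate(i: int, start_km: float, start_n: float, n_cen: int) -> tuple[float, float]:
        """Distribute n_cen censorings evenly over interval i, derive event
        counts at clicks, return (n at next interval start, km there)."""
        lo, up = lower[i], upper[i]
        t_end = rtimes[i + 1] if i + 1 < nint else t[-1]
        if n_cen > 0:
            cen_times = rtimes[i] + (np.arange(1, n_cen + 1) / (n_cen + 1)) * (
                t_end - rtimes[i]
            )
        else:
            cen_times = np.empty(0)
        cur_km = start_km
        # censorings falling before the interval's first click leave the
        # risk set before any event there
        pre_cen = int(np.sum(cen_times < t[lo])) if lo < K else 0
        n_hat[lo] = start_n - pre_cen
        for k in range(lo, up + 1):
            if k == 0:
                d[k] = 0
            else:
                if cur_km <= 0:
                    d[k] = 0
                elif n_hat[k] <= 0:
                    d[k] = 0
                else:
                    d[k] = int(round(n_hat[k] * (1.0 - S[k] / cur_km)))
                d[k] = max(0, min(d[k], int(round(n_hat[k]))))
            if n_hat[k] > 0:
                cur_km = cur_km * (1.0 - d[k] / n_hat[k])
            km[k] = cur_km
            hi = t[k + 1] if k + 1 < K else np.inf
            cens_k[k] = int(np.sum((cen_times >= t[k]) & (cen_times < hi)))
            n_hat[k + 1] = n_hat[k] - d[k] - cens_k[k]
        return n_hat[up + 1], cur_km

    cen_counts = np.zeros(nint, dtype=int)
    start_km, start_n = 1.0, float(rcounts[0])
    for i in range(nint):
        lo = lower[i]
        if i + 1 < nint:
            nxt = lower[i + 1]
            s_lo = S[lo] if lo < K else S[-1]
            s_nxt = S[nxt] if nxt < K else S[-1]
            guess = int(round(start_n * (s_nxt / s_lo if s_lo > 0 else 0.0)
                              - rcounts[i + 1]))
            n_cen = max(0, guess)
            # iterate: match the published at-risk count at the next time;
            # event counts are integer-rounded, so accept the closest
            # achievable match (tolerance 2) instead of demanding equality
            best: tuple[int, int, float, float] | None = None
            tried: set[int] = set()
            for _ in range(1000):
                end_n, end_km = _propagate(i, start_km, start_n, n_cen)
                diff = int(round(end_n - rcounts[i + 1]))
                if best is None or abs(diff) < abs(best[1]):
                    best = (n_cen, diff, end_n, end_km)
                if diff == 0:
                    break
                tried.add(n_cen)
                n_cen = max(0, n_cen + diff)
                if n_cen in tried:
                    break
            n_cen, diff, end_n, end_km = best
            if abs(diff) > max(3, int(0.1 * start_n)):
                raise ReconstructionError(
                    f"interval {i} ([{rtimes[i]}, {rtimes[i+1]}]): digitized "
                    f"curve and at-risk table are inconsistent (at-risk "
                    f"mismatch {diff} with {n_cen} censorings)"
                )
            if diff != 0:
                # click grid does not align with risk times, so a few exits
                # may be attributed across the boundary; carry the
                # reconstructed count forward
                logger.warning(
                    "interval %d: at-risk mismatch of %d subjects at t=%s",
                    i, diff, rtimes[i + 1],
                )
                end_n, end_km = _propagate(i, start_km, start_n, n_cen)
            cen_counts[i] = n_cen
            start_km, start_n = end_km, end_n
        else:
            # final interval: no interior censoring assumed; survivors are
            # administratively censored at the last click time.
            end_n, end_km = _propagate(i, start_km, start_n, 0)
            if curve.total_events is not None:
                _rescale_final_interval(d, lower[i], upper[i], curve.total_events)
            start_km, start_n = end_km, end_n

    records: list[tuple[float, int]] = []
    for k in range(K):
        if t[k] > 0:
            records.extend([(float(t[k]), 1)] * int(d[k]))
    # censoring times from the per-interval even spread
    for i in range(nint):
        n_cen = cen_counts[i]
        if n_cen <= 0:
            continue
        t_end = rtimes[i + 1] if i + 1 < nint else t[-1]
        cen_times = rtimes[i] + (np.arange(1, n_cen + 1) / (n_cen + 1)) * (
            t_end - rtimes[i]
        )
        records.extend((float(ct), 0) for ct in cen_times if ct > 0)
    # administrative censoring of survivors at the last click
    n_left = int(round(start_n))
    if n_left > 0 and t[-1] > 0:
        records.extend([(float(t[-1]), 0)] * n_left)
    if not records:
        raise ReconstructionError("reconstruction produced no records")
    records.sort()
    return PseudoIPD(records=tuple(records), arm=curve.arm, endpoint=curve.endpoint)


def _rescale_final_interval(d: np.ndarray, lo: int, up: int, total_events: int) -> None:
    """Scale event counts in the final interval so the grand total matches."""
    before = int(d[:lo].sum())
    inside = int(d[lo : up + 1].sum())
    target = max(0, total_events - before)
    if inside == 0 or target == inside:
        return
    scale = target / inside
    d[lo : up + 1] = np.maximum(0, np.round(d[lo : up + 1] * scale)).astype(int)


def km_estimate(ipd: PseudoIPD) -> list[tuple[float, float]]:
    """Product-limit estimate of the survival function.

    Returns the step function as ``(time, survival)`` pairs starting at
    ``(0, 1)`` with one entry per distinct observed time.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    sf = kmf.survival_function_
    return list(zip(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float)))


def km_survival_at(ipd: PseudoIPD, times: Sequence[float]) -> np.ndarray:
    """Evaluate the KM step function of ``ipd`` at arbitrary times."""
    steps = km_estimate(ipd)
    st = np.array([s for s, _ in steps])
    sv = np.array([v for _, v in steps])
    idx = np.searchsorted(st, np.asarray(times, float), side="right") - 1
    idx = np.clip(idx, 0, len(sv) - 1)
    return sv[idx]


def write_ipd_csv(ipd: PseudoIPD, path: str | Path) -> None:
    ipd.to_frame().to_csv(path, index=False)


def read_ipd_csv(path: str | Path) -> PseudoIPD:
    df = pd.read_csv(path)
    arm = str(df["arm"].iloc[0]) if "arm" in df else ""
    endpoint = str(df["endpoint"].iloc[0]) if "endpoint" in df else ""
    return PseudoIPD(
        records=tuple(zip(df["time_months"].astype(float), df["event"].astype(int))),
        arm=arm,
        endpoint=endpoint,
    )
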