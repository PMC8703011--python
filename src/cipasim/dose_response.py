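"""Hill-equation fitting and bootstrap uncertainty quantification.

Fractional block of a channel at drug concentration D (nM) is modelled as

    block(D) = 1 / (1 + (IC50 / D)^h),

the complement of the remaining-conductance inhibition factor.  ``fit_hill``
is a least-squares fit in (log10 IC50, h) space; ``bootstrap_hill`` draws
case-resampled refits and trims them to the joint central-95% box so that a
sample set emulates "2,000 Hill curves within the 95% confidence interval".

Channels for which a drug shows no measurable block carry the no-block
sentinel (IC50 = +inf, h = 1), which makes the inhibition factor exactly 1 at
every concentration; every drug sample therefore always covers all six
channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

CHANNELS = ("INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")

_H_BOUNDS = (0.2, 10.0)  # Hill coefficient bounds during optimization
_LOG_IC50_BOUNDS = (-3.0, 9.0)  # log10 nM


class FittingError(RuntimeError):
    pass


@dataclass(frozen=True)
class HillParams:
    """One channel's block parameters: IC50 (nM) and Hill coefficient h.

    ``no_block=True`` marks the sentinel for channels without measurable
    block (ic50 = +inf, h = 1).
    """

    ic50: float
    h: float
    no_block: bool = False

    def __post_init__(self):
        if not (self.ic50 > 0):
            raise ValueError("ic50 must be > 0")
        if not (self.h > 0):
            raise ValueError("h must be > 0")


NO_BLOCK_SENTINEL = HillParams(ic50=math.inf, h=1.0, no_block=True)


def hill_block(d, ic50: float, h: float):
    """Fractional block at concentration(s) ``d``."""
    d = np.asarray(d, dtype=float)
    if math.isinf(ic50):
        return np.zeros_like(d)
    return 1.0 / (1.0 + (ic50 / d) ** h)


@dataclass
class DoseResponseTable:
    """Per-replicate fractional-block measurements for one channel."""

    channel: str
    data: pd.DataFrame  # columns: conc_nM, block_frac, replicate

    def __post_init__(self):
        required = {"conc_nM", "block_frac", "replicate"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        if (self.data["conc_nM"] <= 0).any():
            raise ValueError("concentrations must be strictly positive")

    @property
    def n_distinct_doses(self) -> int:
        return self.data["conc_nM"].nunique()


@dataclass
class DrugSampleSet:
    """Bootstrap parameter draws for one drug: ``samples[i][channel]``."""

    drug: str
    samples: list  # list of dict channel -> HillParams
    cmax: float  # free Cmax, nM
    risk_label: str
    warnings: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _fit_arrays(conc: np.ndarray, block: np.ndarray) -> HillParams:
    logd = np.log10(conc)

    def resid(p):
        return 1.0 / (1.0 + 10.0 ** (p[0] * p[1] - p[1] * logd)) - block

    # start at the dose nearest half-block, h = 1
    i0 = int(np.argmin(np.abs(block - 0.5)))
    x0 = np.array([np.clip(logd[i0], *_LOG_IC50_BOUNDS), 1.0])
    sol = least_squares(
        resid,
        x0,
        bounds=([_LOG_IC50_BOUNDS[0], _H_BOUNDS[0]],
                [_LOG_IC50_BOUNDS[1], _H_BOUNDS[1]]),
        method="trf",
    )
    if not sol.success:
        raise FittingError(f"Hill fit did not converge: {sol.message}")
    return HillParams(ic50=10.0 ** sol.x[0], h=float(sol.x[1]))


def _looks_blockless(conc: np.ndarray, block: np.ndarray) -> bool:
    """No measurable, dose-increasing block anywhere."""
    if np.nanmax(block) <= 0.01:
        return True
    order = np.argsort(conc)
    by_dose = pd.Series(block[order]).groupby(conc[order]).mean()
    return bool(by_dose.iloc[-1] <= by_dose.iloc[0])


def fit_hill(table: DoseResponseTable) -> HillParams:
    """Least-squares (IC50, h) in log-IC50 space.

    A channel with no measurable block returns the no-block sentinel.
    """
    df = table.data.dropna(subset=["conc_nM", "block_frac"])
    if df["conc_nM"].nunique() < 4:
        raise ValueError("need >= 4 distinct doses with finite block values")
    conc = df["conc_nM"].to_numpy(dtype=float)
    block = df["block_frac"].to_numpy(dtype=float)
    if _looks_blockless(conc, block):
        return NO_BLOCK_SENTINEL
    return _fit_arrays(conc, block)


def bootstrap_hill(
    table: DoseResponseTable, n: int = 2000, seed: int = 0
) -> list[HillParams]:
    """``n`` case-resampled refits trimmed to the joint central-95% box.

    Rows are resampled with replacement and refit; fits falling outside the
    2.5-97.5 percentile box of (log10 IC50, h) are dropped and replaced by
    further resamples until exactly ``n`` are retained.
    """
    point = fit_hill(table)
    df = table.data.dropna(subset=["conc_nM", "block_frac"])
    if len(df) < 8:
        raise ValueError("table too small to resample (< 8 rows)")
    if point.no_block:
        return [NO_BLOCK_SENTINEL] * n
    conc = df["conc_nM"].to_numpy(dtype=float)
    block = df["block_frac"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    nrow = len(conc)

    def draw_batch(k):
        out = []
        while len(out) < k:
            idx = rng.integers(0, nrow, size=nrow)
            if len(np.unique(conc[idx])) < 4:
                continue
            try:
                out.append(_fit_arrays(conc[idx], block[idx]))
            except FittingError:
                continue
        return out

    pool = draw_batch(n)
    log_ic50 = np.log10([p.ic50 for p in pool])
    hs = np.array([p.h for p in pool])
    # the 95% box is fixed by the initial n fits; resample until n fall inside
    lo_i, hi_i = np.percentile(log_ic50, [2.5, 97.5])
    lo_h, hi_h = np.percentile(hs, [2.5, 97.5])

    def inside(p: HillParams) -> bool:
        return (lo_i <= math.log10(p.ic50) <= hi_i) and (lo_h <= p.h <= hi_h)

    keep = [p for p in pool if inside(p)]
    while len(keep) < n:
        keep.extend(p for p in draw_batch(n - len(keep)) if inside(p))
    return keep[:n]


def fit_drug(
    tables: Mapping[str, DoseResponseTable],
    cmax: float,
    risk_label: str,
    drug: str = "drug",
    n_samples: int = 2000,
    seed: int = 0,
) -> DrugSampleSet:
    """Bootstrap sample set over all six channels for one drug.

    Channels absent from ``tables`` (or without measurable block) carry the
    no-block sentinel in every sample, so each sample covers all six channels.
    """
    per_channel: dict[str, list[HillParams]] = {}
    warnings: dict[str, str] = {}
    rng = np.random.default_rng(seed)
    for ch in CHANNELS:
        if ch not in tables:
            per_channel[ch] = [NO_BLOCK_SENTINEL] * n_samples
            warnings[ch] = "no data; no-block sentinel"
            continue
        draws = bootstrap_hill(
            tables[ch], n=n_samples, seed=int(rng.integers(0, 2**31 - 1))
        )
        per_channel[ch] = draws
        if draws[0].no_block:
            warnings[ch] = "no measurable block; sentinel"
    samples = [
        {ch: per_channel[ch][i] for ch in CHANNELS} for i in range(n_samples)
    ]
    return DrugSampleSet(
        drug=drug, samples=samples, cmax=cmax, risk_label=risk_label,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# CSV interfaces (layout mirrors the supplementary sample-set tables)


def samples_to_frame(sets: Sequence[DrugSampleSet]) -> pd.DataFrame:
    rows = []
    for ss in sets:
        for i, sample in enumerate(ss.samples):
            for ch in CHANNELS:
                p = sample[ch]
                rows.append(
                    {
                        "drug": ss.drug,
                        "sample_id": i,
                        "channel": ch,
                        "ic50_nM": p.ic50,
                        "hill": p.h,
                    }
                )
    return pd.DataFrame(rows)


def frame_to_samples(
    df: pd.DataFrame, meta: pd.DataFrame
) -> list[DrugSampleSet]:
    """Inverse of :func:`samples_to_frame`; ``meta`` columns: drug, cmax_nM,
    label."""
    meta = meta.set_index("drug")
    sets = []
    for drug, g in df.groupby("drug", sort=False):
        samples = []
        for _, sg in g.groupby("sample_id", sort=True):
            by_ch = sg.set_index("channel")
            sample = {}
            for ch in CHANNELS:
                if ch in by_ch.index:
                    r = by_ch.loc[ch]
                    ic50 = float(r["ic50_nM"])
                    sample[ch] = (
                        NO_BLOCK_SENTINEL
                        if math.isinf(ic50)
                        else HillParams(ic50=ic50, h=float(r["hill"]))
                    )
                else:
                    sample[ch] = NO_BLOCK_SENTINEL
            samples.append(sample)
        sets.append(
            DrugSampleSet(
                drug=str(drug),
                samples=samples,
                cmax=float(meta.loc[drug, "cmax_nM"]),
                risk_label=str(meta.loc[drug, "label"]),
            )
        )
    return sets
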