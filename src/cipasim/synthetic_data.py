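"""Synthetic drugs, dose-response tables and toy beats with known truth.

The generator stands in for the CiPA 28-drug patch-clamp panel so the whole
pipeline is testable without external data.  Class structure follows the known
pharmacology of the panel anchors:

* high risk  - potent, selective hERG (IKr) block well below Cmax with weak
  inward-current block (quinidine/dofetilide-like);
* low risk   - either balanced block where strong ICaL/INaL block offsets
  moderate IKr block (verapamil-like), or negligible block at Cmax
  (metoprolol-like);
* intermediate - moderate IKr block near Cmax with mild inward block.

All concentrations are nanomolar.  Dose-response noise is additive Gaussian on
fractional block, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import (
    CHANNELS,
    DoseResponseTable,
    HillParams,
    hill_block,
)

RISK_CLASSES = ("high", "intermediate", "low")


@dataclass(frozen=True)
class SyntheticDrug:
    name: str
    true_params: Mapping[str, HillParams]  # all six channels
    cmax: float  # nM
    risk_label: str
    split: str = "TESTING"  # TRAINING | TESTING

    def __post_init__(self):
        if self.risk_label not in RISK_CLASSES:
            raise ValueError(f"unknown risk label {self.risk_label!r}")
        for ch, p in self.true_params.items():
            if not p.no_block and not (0.5 <= p.h <= 4.0):
                raise ValueError(f"{ch}: h outside [0.5, 4]")


@dataclass(frozen=True)
class ToyBeatSpec:
    """Piecewise-linear AP/CaT with analytically known biomarkers."""

    v_rest: float = -88.0  # mV
    v_peak: float = 32.0  # mV
    apd_true: float = 300.0  # ms: time from upstroke to 100% repolarization
    ca_rest: float = 1.0e-4  # mM
    ca_peak: float = 5.0e-4  # mM
    cad_true: float = 400.0  # ms
    bcl: float = 2000.0  # ms

    def __post_init__(self):
        if self.v_peak <= self.v_rest:
            raise ValueError("v_peak must exceed v_rest")
        if self.ca_peak <= self.ca_rest:
            raise ValueError("ca_peak must exceed ca_rest")
        if self.apd_true >= self.bcl:
            raise ValueError("apd_true must be < bcl")
        if self.cad_true >= self.bcl:
            raise ValueError("cad_true must be < bcl")


def gen_dose_response(
    truth: HillParams,
    doses: Sequence[float],
    noise_sd: float,
    seed: int,
    n_replicates: int = 1,
) -> DoseResponseTable:
    """Noisy fractional-block table: Hill mean + clipped Gaussian noise.

    With ``noise_sd == 0`` the table is exactly the Hill function at every
    dose.  Reproducible under a fixed seed.
    """
    doses = np.asarray(list(doses), dtype=float)
    if doses.size == 0:
        raise ValueError("dose list must not be empty")
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        mean = hill_block(doses, truth.ic50, truth.h)
        block = mean + rng.normal(0.0, noise_sd, size=doses.size) if noise_sd else mean
        block = np.clip(block, 0.0, 1.0)
        for d, b in zip(doses, block):
            rows.append({"conc_nM": d, "block_frac": b, "replicate": rep})
    return DoseResponseTable(channel="", data=pd.DataFrame(rows))


def _log_uniform(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_params(rng, potency_ratio_range, cmax) -> HillParams:
    """IC50 drawn as a multiple of Cmax; h uniform on a physiological range."""
    ratio = _log_uniform(rng, *potency_ratio_range)
    return HillParams(ic50=ratio * cmax, h=float(rng.uniform(0.7, 2.0)))


# IC50 / Cmax ratio ranges per class and channel.  "weak" channels barely
# block over the simulated 1-4x Cmax range.
_WEAK = (30.0, 300.0)
_PROFILES = {
    "high": {"IKr": (0.3, 0.7), "ICaL": _WEAK, "INaL": _WEAK},
    "intermediate": {"IKr": (1.0, 3.0), "ICaL": (10.0, 30.0), "INaL": (10.0, 30.0)},
    # two low-risk subtypes, alternating: balanced (verapamil-like) and
    # negligible-block (metoprolol-like)
    "low_balanced": {"IKr": (1.5, 4.0), "ICaL": (0.4, 1.0), "INaL": (2.0, 8.0)},
    "low_clean": {"IKr": (8.0, 30.0), "ICaL": (8.0, 40.0), "INaL": _WEAK},
}


def _make_drug(rng, name: str, risk: str, subtype: str) -> SyntheticDrug:
    cmax = _log_uniform(rng, 30.0, 3000.0)
    profile = _PROFILES[subtype]
    params = {}
    for ch in CHANNELS:
        rng_range = profile.get(ch, _WEAK)
        params[ch] = _draw_params(rng, rng_range, cmax)
    return SyntheticDrug(
        name=name, true_params=params, cmax=cmax, risk_label=risk
    )


def gen_drug_library(n_per_class: int, seed: int) -> list[SyntheticDrug]:
    """``3 * n_per_class`` class-structured synthetic drugs, deterministic
    under ``seed``."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    drugs = []
    for risk in RISK_CLASSES:
        for i in range(n_per_class):
            subtype = risk
            if risk == "low":
                subtype = "low_balanced" if i % 2 == 0 else "low_clean"
            drugs.append(_make_drug(rng, f"{risk}_{i:02d}", risk, subtype))
    return drugs


def gen_drug_panel(
    seed: int,
    n_train_per_class: int = 4,
    n_test: tuple[int, int, int] = (5, 6, 5),
) -> list[SyntheticDrug]:
    """Train/test panel mirroring the 12 + 16 drug layout: ``n_train_per_class``
    drugs per class marked TRAINING plus ``n_test`` (high, intermediate, low)
    marked TESTING."""
    rng = np.random.default_rng(seed)
    drugs = []
    for risk, extra in zip(RISK_CLASSES, n_test):
        for i in range(n_train_per_class + extra):
            subtype = risk
            if risk == "low":
                subtype = "low_balanced" if i % 2 == 0 else "low_clean"
            split = "TRAINING" if i < n_train_per_class else "TESTING"
            d = _make_drug(rng, f"{risk}_{i:02d}", risk, subtype)
            drugs.append(
                SyntheticDrug(
                    name=d.name, true_params=d.true_params, cmax=d.cmax,
                    risk_label=risk, split=split,
                )
            )
    return drugs


def gen_toy_beat(spec: ToyBeatSpec, dt: float = 0.1):
    """Instantaneous-rise, linear-decay AP and CaT on a uniform grid.

    The waveform rises from rest to peak over one time step at t = dt and
    decays linearly back to rest over ``apd_true`` (``cad_true``), so the x%
    repolarization level is crossed at x% of the true duration: APD90 =
    0.9 * apd_true, APD50 = 0.5 * apd_true, and analogously for calcium.
    """
    from .cardiac_sim import PacedTrace  # local import to avoid cycle

    if not (0 < dt <= 0.1):
        raise ValueError("dt must be in (0, 0.1] ms")
    t = np.arange(0.0, spec.bcl + dt / 2, dt)

    def wave(rest, peak, dur_true):
        y = np.full_like(t, rest)
        rise_t = dt
        decay = (t >= rise_t) & (t <= rise_t + dur_true)
        y[decay] = peak - (peak - rest) * (t[decay] - rise_t) / dur_true
        y[0] = rest
        return y

    vm = wave(spec.v_rest, spec.v_peak, spec.apd_true)
    cai = wave(spec.ca_rest, spec.ca_peak, spec.cad_true)
    zeros = np.zeros_like(t)
    return PacedTrace(
        t=t,
        vm=vm,
        cai=cai,
        currents={c: zeros.copy() for c in CHANNELS},
        auc_inal=0.0,
        auc_ical=0.0,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def library_to_frames(
    drugs: Sequence[SyntheticDrug],
    doses_per_cmax: Sequence[float] = (0.25, 0.75, 2.0, 6.0, 18.0, 54.0),
    n_replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(dose-response table, drug metadata) frames for a synthetic panel.

    Dose-response columns: drug, channel, conc_nM, block_frac, replicate.
    Metadata columns: drug, cmax_nM, label, split.
    """
    rng = np.random.default_rng(seed)
    dr_rows = []
    meta_rows = []
    for d in drugs:
        meta_rows.append(
            {"drug": d.name, "cmax_nM": d.cmax, "label": d.risk_label,
             "split": d.split}
        )
        doses = [m * d.cmax for m in doses_per_cmax]
        for ch in CHANNELS:
            tab = gen_dose_response(
                d.true_params[ch], doses, noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                n_replicates=n_replicates,
            )
            for _, r in tab.data.iterrows():
                dr_rows.append(
                    {"drug": d.name, "channel": ch, "conc_nM": r["conc_nM"],
                     "block_frac": r["block_frac"],
                     "replicate": int(r["replicate"])}
                )
    return pd.DataFrame(dr_rows), pd.DataFrame(meta_rows)


def frames_to_tables(dr: pd.DataFrame) -> dict[str, dict[str, DoseResponseTable]]:
    """Group a dose-response frame into ``tables[drug][channel]``."""
    out: dict[str, dict[str, DoseResponseTable]] = {}
    for (drug, ch), g in dr.groupby(["drug", "channel"], sort=False):
        out.setdefault(str(drug), {})[str(ch)] = DoseResponseTable(
            channel=str(ch),
            data=g[["conc_nM", "block_frac", "replicate"]].reset_index(drop=True),
        )
    return out
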