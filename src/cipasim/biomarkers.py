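"""Representative-beat selection and the nine TdP-risk biomarkers.

From each recorded beat set the single most proarrhythmic action potential is
selected: among beats that neither fail to depolarize (peak Vm < 0 mV) nor
fail to repolarize (Vm never returns below the 90% repolarization level within
the cycle), the beat maximizing the steepest repolarization-window dVm/dt is
chosen.  A beat carrying an early afterdepolarization shows a large positive
dVm/dt between its peak and the end of the cycle, so this rule deliberately
picks the worst beat.

The nine features: dVm/dt_max (upstroke), AP_resting, APD90, APD50,
Ca_resting, CaD90, CaD50, qNet and qInward.  Durations are measured from the
instant of maximal upstroke slope to the crossing of
peak - x% * (peak - resting).  qNet is the trapezoidal integral of
(INaL + ICaL + IKr + IKs + IK1 + Ito) over the full cycle, reported in uC/uF;
qInward is the mean of the drug/control AUC ratios of ICaL and INaL and equals
1 exactly for a drug-free beat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cardiac_sim import PacedTrace

FEATURE_NAMES = (
    "dvmdt_max", "ap_resting", "apd90", "apd50",
    "ca_resting", "cad90", "cad50", "qnet", "qinward",
)

#: select_ap marker when no beat in the window is usable
NO_VALID_BEAT = -1


@dataclass(frozen=True)
class FeatureVector:
    dvmdt_max: float  # mV/ms
    ap_resting: float  # mV
    apd90: float  # ms
    apd50: float  # ms
    ca_resting: float  # mM
    cad90: float  # ms
    cad50: float  # ms
    qnet: float  # uC/uF
    qinward: float  # dimensionless

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES])


@dataclass(frozen=True)
class BeatStatus:
    status: str  # ok | depol_fail | repol_fail
    dvmdt_max_repol: float = math.nan  # defined only when ok

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _crossing_time(t, y, level, start_idx):
    """First time at/after ``start_idx`` where ``y`` falls to ``level``
    (linear interpolation); NaN if never."""
    below = y[start_idx:] <= level
    if not below.any():
        return math.nan
    j = start_idx + int(np.argmax(below))
    if j == start_idx or y[j - 1] == y[j]:
        return t[j]
    w = (y[j - 1] - level) / (y[j - 1] - y[j])
    return t[j - 1] + w * (t[j] - t[j - 1])


def classify_beat(trace: PacedTrace) -> BeatStatus:
    vm = trace.vm
    peak_idx = int(np.argmax(vm))
    peak = vm[peak_idx]
    if peak < 0.0:
        return BeatStatus("depol_fail")
    rest = vm[0]
    level90 = peak - 0.9 * (peak - rest)
    t90 = _crossing_time(trace.t, vm, level90, peak_idx)
    if math.isnan(t90):
        return BeatStatus("repol_fail")
    # window from the AP peak to end of cycle; the gradient sample at the
    # peak itself straddles the upstroke, so the window starts just after it
    dvdt = np.gradient(vm, trace.t)
    start = min(peak_idx + 1, len(vm) - 1)
    return BeatStatus("ok", dvmdt_max_repol=float(dvdt[start:].max()))


def select_ap(traces: Sequence[PacedTrace]) -> int:
    """Index of the ok beat maximizing dVm/dt_max_repol (earliest on ties);
    :data:`NO_VALID_BEAT` if every beat failed."""
    if len(traces) == 0:
        raise ValueError("empty trace list")
    best = NO_VALID_BEAT
    best_val = -math.inf
    for i, tr in enumerate(traces):
        st = classify_beat(tr)
        if st.ok and st.dvmdt_max_repol > best_val:
            best = i
            best_val = st.dvmdt_max_repol
    return best


def _duration(t, y, anchor_t, peak_idx, frac):
    peak = y[peak_idx]
    rest = y[0]
    level = peak - frac * (peak - rest)
    tc = _crossing_time(t, y, level, peak_idx)
    return tc - anchor_t


def compute_features(
    beat: PacedTrace,
    control_auc: tuple[float, float],
    bcl: float,
) -> FeatureVector:
    """Nine biomarkers of one ok beat.

    ``control_auc`` is (AUC_INaL, AUC_ICaL) from the matching drug-free run.
    """
    if control_auc is None:
        raise ValueError("control AUCs are required")
    status = classify_beat(beat)
    if not status.ok:
        raise ValueError(f"cannot compute features of a {status.status} beat")

    t = beat.t
    vm = beat.vm
    cai = beat.cai
    dvdt = np.gradient(vm, t)
    vpeak_idx = int(np.argmax(vm))
    up_idx = int(np.argmax(dvdt[: vpeak_idx + 1]))
    anchor_t = t[up_idx]
    dvmdt_max = float(dvdt[up_idx])
    ap_resting = float(vm[0])
    apd90 = _duration(t, vm, anchor_t, vpeak_idx, 0.9)
    apd50 = _duration(t, vm, anchor_t, vpeak_idx, 0.5)

    dcadt = np.gradient(cai, t)
    capeak_idx = int(np.argmax(cai))
    ca_up_idx = int(np.argmax(dcadt[: capeak_idx + 1]))
    ca_anchor = t[ca_up_idx]
    ca_resting = float(cai[0])
    cad90 = _duration(t, cai, ca_anchor, capeak_idx, 0.9)
    cad50 = _duration(t, cai, ca_anchor, capeak_idx, 0.5)

    # qNet: trapezoidal integral of the six-current sum over [0, BCL].
    # Simulator beats carry the solver-resolution accumulation (the output
    # grid decimates the upstroke, where the currents sweep their whole I-V
    # range in well under 0.1 ms); synthetic fixtures without it fall back to
    # integrating the recorded grid.
    if math.isfinite(beat.fine_qnet_sum):
        qnet = beat.fine_qnet_sum / 1000.0  # uC/uF
    else:
        mask = t <= bcl + 1e-9
        total = sum(beat.currents[c] for c in beat.currents)
        qnet = float(np.trapezoid(total[mask], t[mask])) / 1000.0

    auc_inal_c, auc_ical_c = control_auc
    if auc_inal_c == 0.0 and beat.auc_inal == 0.0:
        r_inal = 1.0
    else:
        r_inal = beat.auc_inal / auc_inal_c
    if auc_ical_c == 0.0 and beat.auc_ical == 0.0:
        r_ical = 1.0
    else:
        r_ical = beat.auc_ical / auc_ical_c
    qinward = 0.5 * (r_ical + r_inal)

    return FeatureVector(
        dvmdt_max=dvmdt_max, ap_resting=ap_resting,
        apd90=float(apd90), apd50=float(apd50),
        ca_resting=ca_resting, cad90=float(cad90), cad50=float(cad50),
        qnet=qnet, qinward=float(qinward),
    )


def average_concentrations(
    fvs: Sequence[FeatureVector | None],
) -> FeatureVector | None:
    """Element-wise mean over the four concentration multiples (1-4x Cmax);
    ``None`` (flagged missing) if any concentration had no valid beat."""
    if len(fvs) != 4:
        raise ValueError("exactly four concentration feature vectors required")
    if any(fv is None for fv in fvs):
        return None
    mean = np.mean([fv.to_array() for fv in fvs], axis=0)
    return FeatureVector(**dict(zip(FEATURE_NAMES, map(float, mean))))
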