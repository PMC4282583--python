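"""Time-series analysis of bond-vector and dihedral trajectories.

Internal C-H reorientational dynamics are characterised by the P2
autocorrelation function

    C(t) = < P2( u(s) . u(s+t) ) >,   P2(x) = (3 x^2 - 1) / 2

computed after the overall rotation/translation of the molecule has been
removed by superposing a rigid four-atom backbone anchor onto a reference
frame (by default the midpoint of the trajectory).  The plateau and decay
of C(t) are summarised by the Lipari-Szabo model

    C(t) = S^2 + (1 - S^2) exp(-t / tau_e)

fitted over an initial window.  Torsional kinetics are summarised by a
hysteresis-based transition counter (no state change is registered until
the opposite core region is entered, so within-state libration does not
chatter) and by state populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .ringgeom import superpose_fragment

__all__ = [
    "VectorSeries",
    "AcfCurve",
    "LipariSzaboModel",
    "LipariSzaboResults",
    "remove_overall_motion",
    "acf_p2",
    "lipari_szabo_fit",
    "transition_count",
    "state_populations",
    "sign_state_rule",
]


@dataclass
class VectorSeries:
    """Unit bond vectors sampled on a uniform time grid (dt in ps)."""

    vectors: np.ndarray
    dt_ps: float

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("vectors must be (n_frames, 3)")
        if self.dt_ps <= 0:
            raise ValueError("dt must be positive")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("vectors must be unit norm within 1e-6")

    def __len__(self):
        return len(self.vectors)

    @classmethod
    def from_tsv(cls, path, dt_ps=None) -> "VectorSeries":
        """Read (time_ps, x, y, z) rows; dt inferred from the time column."""
        df = pd.read_csv(path, sep="\t")
        t = df.iloc[:, 0].to_numpy(float)
        v = df.iloc[:, 1:4].to_numpy(float)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        if dt_ps is None:
            dt_ps = float(np.median(np.diff(t)))
        return cls(vectors=v, dt_ps=dt_ps)


@dataclass
class AcfCurve:
    """Normalised P2 autocorrelation curve: C(0) = 1."""

    lags_ps: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.lags_ps = np.asarray(self.lags_ps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if abs(self.values[0] - 1.0) > 1e-6:
            raise ValueError("C(0) must be 1 after normalisation")

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.lags_ps, self.values, **kw)
        ax.set_xlabel("lag (ps)")
        ax.set_ylabel("C(t)")
        return ax


def remove_overall_motion(frames, anchor, reference: int | None = None):
    """Superpose every frame onto a reference frame on the anchor atoms.

    ``frames`` is (n_frames, n_atoms, 3); ``anchor`` gives >= 3 atom indices
    (the rigid C-N-CA-C backbone fragment); ``reference`` defaults to the
    midpoint frame.  Returns (aligned frames, per-frame anchor rmsd).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, n_atoms, 3)")
    n = len(frames)
    ref_idx = n // 2 if reference is None else int(reference)
    ref = frames[ref_idx]
    anchor = list(anchor)
    out = np.empty_like(frames)
    rmsd = np.empty(n)
    for i, f in enumerate(frames):
        tr = superpose_fragment(f, ref, indices=anchor)
        out[i] = tr.apply(f)
        rmsd[i] = tr.rmsd
    return out, rmsd


def acf_p2(v: VectorSeries, max_lag_ps: float) -> AcfCurve:
    """P2 autocorrelation over all overlapping time origins.

    Uses the spherical-harmonic identity P2(u.v) = (4pi/5) sum_m Y2m(u)
    conj(Y2m(v)) so the five cross-correlations are evaluated with FFTs;
    the estimator averages all n - k origin pairs at lag k.
    """
    n = len(v)
    if n == 0:
        raise ValueError("empty series")
    max_lag = int(round(max_lag_ps / v.dt_ps))
    if max_lag >= n:
        raise ValueError("max_lag must be shorter than the series")
    x, y, z = v.vectors.T
    # real second-rank components with sum_c c_i^2 weights reproducing P2
    comps = [
        np.sqrt(3.0) * x * y,
        np.sqrt(3.0) * x * z,
        np.sqrt(3.0) * y * z,
        0.5 * np.sqrt(3.0) * (x**2 - y**2),
        0.5 * (3.0 * z**2 - 1.0),
    ]
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    acc = np.zeros(max_lag + 1)
    for c in comps:
        f = np.fft.rfft(c, nfft)
        corr = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
        acc += corr
    counts = n - np.arange(max_lag + 1)
    cvals = acc / counts
    cvals = cvals / cvals[0]
    lags = np.arange(max_lag + 1) * v.dt_ps
    return AcfCurve(lags_ps=lags, values=cvals)


# ---------------------------------------------------------------------------
# Lipari-Szabo fit


@dataclass
class LipariSzaboResults:
    s2: float
    tau_e_ps: float
    window_ps: float
    rms: float
    tau_identifiable: bool = True

    def summary(self) -> str:
        lines = [
            "Lipari-Szabo fit  C(t) = S2 + (1-S2) exp(-t/tau_e)",
            "-" * 50,
            f"  S^2    : {self.s2:8.4f}",
            f"  tau_e  : {self.tau_e_ps:8.2f} ps"
            + ("" if self.tau_identifiable else "  (unidentifiable: flat curve)"),
            f"  window : {self.window_ps:8.1f} ps",
            f"  rms    : {self.rms:8.2e}",
        ]
        return "\n".join(lines)


class LipariSzaboModel:
    """Model-free fit of an internal P2 autocorrelation curve."""

    def __init__(self, curve: AcfCurve, window_ps: float = 20000.0):
        mask = curve.lags_ps <= window_ps
        if mask.sum() < 3:
            raise ValueError("window must contain at least 3 lags")
        self.lags = curve.lags_ps[mask]
        self.values = curve.values[mask]
        self.window_ps = float(min(window_ps, curve.lags_ps[-1]))

    @staticmethod
    def _model(t, s2, tau):
        return s2 + (1.0 - s2) * np.exp(-t / tau)

    def fit(self) -> LipariSzaboResults:
        spread = float(self.values[0] - self.values[-1])
        if spread < 1e-9:
            # flat curve: S2 = C, tau has no effect
            return LipariSzaboResults(
                s2=float(np.clip(np.mean(self.values), 0.0, 1.0)),
                tau_e_ps=float("nan"), window_ps=self.window_ps,
                rms=float(np.std(self.values)), tau_identifiable=False,
            )
        s2_0 = float(np.clip(self.values[-1], 0.0, 0.999))
        # initial tau: lag where the decaying part falls to 1/e
        decay = (self.values - s2_0) / max(1.0 - s2_0, 1e-9)
        below = np.nonzero(decay < np.exp(-1.0))[0]
        tau_0 = float(self.lags[below[0]]) if len(below) else float(self.lags[-1] / 2)
        tau_0 = max(tau_0, self.lags[1] / 10 if len(self.lags) > 1 else 1e-3)
        try:
            popt, _ = curve_fit(
                self._model, self.lags, self.values, p0=(s2_0, tau_0),
                bounds=([0.0, 1e-6], [1.0, np.inf]), maxfev=20000,
            )
        except RuntimeError as err:
            resid = self.values - self._model(self.lags, s2_0, tau_0)
            raise RuntimeError(
                f"Lipari-Szabo fit failed to converge (initial rms "
                f"{float(np.sqrt(np.mean(resid**2))):.3e})") from err
        s2, tau = popt
        resid = self.values - self._model(self.lags, *popt)
        return LipariSzaboResults(
            s2=float(np.clip(s2, 0.0, 1.0)), tau_e_ps=float(tau),
            window_ps=self.window_ps, rms=float(np.sqrt(np.mean(resid**2))),
        )


def lipari_szabo_fit(curve: AcfCurve, window_ps: float = 20000.0) -> LipariSzaboResults:
    return LipariSzaboModel(curve, window_ps=window_ps).fit()


# ---------------------------------------------------------------------------
# Torsional transitions and state populations


def sign_state_rule(core_deg: float = 10.0):
    """Two-state rule on the sign of chi2 with hysteresis cores |chi2| >= core.

    Returns a callable mapping a dihedral series (degrees) to +1 (exo-like,
    chi2 >= +core), -1 (endo-like, chi2 <= -core) or 0 (band).
    """

    def rule(series):
        s = np.asarray(series, dtype=float)
        out = np.zeros(len(s), dtype=int)
        out[s >= core_deg] = 1
        out[s <= -core_deg] = -1
        return out

    return rule


def _assign_states(series, state_rule):
    raw = state_rule(np.asarray(series, dtype=float))
    states = np.array(raw)
    # carry the last definite state through the hysteresis band
    last = 0
    for i in range(len(states)):
        if states[i] == 0:
            states[i] = last
        else:
            last = states[i]
    if states[0] == 0:
        # leading band frames inherit the first definite state
        definite = states[states != 0]
        if len(definite):
            states[: np.argmax(states != 0)] = definite[0]
    return states


def transition_count(series, state_rule=None, stride_ps: float = 1.0) -> float:
    """Torsional transitions per ns under the hysteresis state rule.

    ``series`` is a dihedral time series (degrees) sampled every
    ``stride_ps``; the default rule thresholds chi2 at +-10 degrees.
    """
    if state_rule is None:
        state_rule = sign_state_rule()
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ValueError("series shorter than one stride")
    states = _assign_states(series, state_rule)
    changes = int(np.sum((states[1:] != states[:-1]) & (states[:-1] != 0)))
    duration_ns = (len(series) - 1) * stride_ps / 1000.0
    return changes / duration_ns


def state_populations(series, state_rule=None) -> float:
    """Fraction of frames in the endo (-1) state; band frames inherit the last state."""
    if state_rule is None:
        state_rule = sign_state_rule()
    series = np.asarray(series, dtype=float)
    if len(series) == 0:
        raise ValueError("empty series")
    states = _assign_states(series, state_rule)
    return float(np.mean(states == -1))
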