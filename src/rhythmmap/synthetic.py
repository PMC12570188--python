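"""Synthetic rhythm recordings and abstract feature tables with known truth.

The study data (single-lead ECG strips with a cardiologist-confirmed
diagnosis) are not publicly deposited, so every downstream stage of the
pipeline is exercised against simulated recordings whose ground truth is
known by construction:

* **normal sinus rhythm** — low-variance RR intervals with a slow sinusoidal
  (respiratory) modulation, hence strong serial correlation and low pNN50;
* **atrial fibrillation** — "irregularly irregular" i.i.d. RR intervals with
  a wide uniform spread, hence high pNN50/pNN20 and near-zero lag-1
  autocorrelation;
* **paroxysmal AF** — a per-beat two-state Markov chain switching between
  the two regimes, with the hidden state recorded for every beat.

The simulators only aim to reproduce the *RR statistics* that drive the HRV
feature panel; they make no attempt at morphological realism (no P waves,
no fibrillatory waves).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RhythmSpec",
    "BlobSpec",
    "RhythmRecording",
    "simulate_rr_series",
    "render_waveform",
    "simulate_feature_blobs",
    "write_rr_csv",
    "read_rr_csv",
    "write_waveform_csv",
]

RHYTHM_CLASSES = ("normal", "af", "paroxysmal")

#: diagnosis label attached to recordings of each simulated rhythm class
DIAGNOSIS_OF_CLASS = {"normal": "normal", "af": "af", "paroxysmal": "possible_af"}

#: hard physiological floor applied to every generated RR interval (seconds)
RR_FLOOR = 0.25

_CLASS_DEFAULTS = {
    # (mean_rr s, rr_jitter s)
    "normal": (0.85, 0.02),
    "af": (0.70, 0.20),
}

#: respiratory modulation frequency for sinus rhythm (Hz)
RESP_FREQ = 0.25


@dataclass(frozen=True)
class RhythmSpec:
    """Parameters of one simulated recording.

    For ``paroxysmal`` recordings, ``mean_rr``/``rr_jitter`` parameterise the
    sinus-rhythm state and ``af_mean_rr``/``af_rr_jitter`` the AF state;
    ``switch_rates`` are the per-beat transition probabilities
    (P(normal->af), P(af->normal)).
    """

    rhythm_class: str
    duration: float = 60.0
    mean_rr: float | None = None
    rr_jitter: float | None = None
    af_mean_rr: float = 0.70
    af_rr_jitter: float = 0.20
    switch_rates: tuple[float, float] = (0.02, 0.05)
    seed: int = 0

    def resolved(self) -> "RhythmSpec":
        """Fill class-dependent defaults for ``mean_rr`` and ``rr_jitter``."""
        base = "af" if self.rhythm_class == "af" else "normal"
        mean_rr, jitter = _CLASS_DEFAULTS.get(base, _CLASS_DEFAULTS["normal"])
        return dataclasses.replace(
            self,
            mean_rr=self.mean_rr if self.mean_rr is not None else mean_rr,
            rr_jitter=self.rr_jitter if self.rr_jitter is not None else jitter,
        )

    def validate(self) -> "RhythmSpec":
        spec = self.resolved()
        if spec.rhythm_class not in RHYTHM_CLASSES:
            raise ValueError(
                f"rhythm_class must be one of {RHYTHM_CLASSES}, got {spec.rhythm_class!r}"
            )
        if not spec.duration > 0:
            raise ValueError(f"duration must be > 0, got {spec.duration}")
        for name in ("mean_rr", "af_mean_rr"):
            value = getattr(spec, name)
            if not (0.25 < value < 2.0):
                raise ValueError(f"{name} must lie in (0.25, 2.0) s, got {value}")
        for name in ("rr_jitter", "af_rr_jitter"):
            if getattr(spec, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(spec, name)}")
        p_na, p_an = spec.switch_rates
        if not (0 <= p_na <= 1 and 0 <= p_an <= 1):
            raise ValueError(f"switch_rates must be probabilities, got {spec.switch_rates}")
        return spec


@dataclass(frozen=True)
class BlobSpec:
    """Gaussian-mixture fixture in an abstract feature space.

    ``separation`` is the minimum pairwise distance between cluster centers in
    units of the (unit) within-cluster standard deviation.
    """

    n_clusters: int
    dim: int = 5
    separation: float = 8.0
    n_per_cluster: int = 100
    seed: int = 0

    def validate(self) -> "BlobSpec":
        if self.n_clusters < 1:
            raise ValueError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if self.dim < 2:
            raise ValueError(f"dim must be >= 2, got {self.dim}")
        if self.separation < 0:
            raise ValueError(f"separation must be >= 0, got {self.separation}")
        if self.n_per_cluster < 1:
            raise ValueError(f"n_per_cluster must be >= 1, got {self.n_per_cluster}")
        return self


@dataclass
class RhythmRecording:
    """A single-lead rhythm recording held as an RR-interval series.

    ``rr`` are the interbeat intervals in seconds; ``states`` records the
    generating rhythm of each beat (``normal``/``af``) for simulated data.
    An optional sampled waveform can be attached by :func:`render_waveform`.
    """

    rr: np.ndarray
    ecg_id: str = "ecg"
    diagnosis: str | None = None
    states: np.ndarray | None = None
    waveform: np.ndarray | None = None  # shape (n_samples, 2): time_s, mv
    fs: float | None = None

    @property
    def duration(self) -> float:
        """Recording length in seconds (waveform length if one is attached)."""
        if self.waveform is not None:
            return float(self.waveform[-1, 0])
        return float(np.sum(self.rr))

    @property
    def beat_times(self) -> np.ndarray:
        """Cumulative beat times in seconds; beat i ends interval rr[i]."""
        return np.cumsum(self.rr)


def _draw_normal_rr(rng, mean_rr, jitter, t):
    # respiratory sinus arrhythmia: amplitude tied to jitter so the
    # zero-noise spec degenerates to a constant series
    amp = 2.0 * jitter
    rr = mean_rr + amp * np.sin(2 * np.pi * RESP_FREQ * t) + rng.normal(0.0, jitter)
    while rr < RR_FLOOR:
        rr = mean_rr + amp * np.sin(2 * np.pi * RESP_FREQ * t) + rng.normal(0.0, jitter)
    return rr


def _draw_af_rr(rng, mean_rr, jitter):
    rr = mean_rr + rng.uniform(-jitter, jitter)
    while rr < RR_FLOOR:
        rr = mean_rr + rng.uniform(-jitter, jitter)
    return rr


def simulate_rr_series(spec: RhythmSpec) -> RhythmRecording:
    """Simulate an RR-interval series for one recording.

    Beats are generated until the cumulative time covers ``spec.duration``.
    Identical specs (including the seed) produce identical output.
    """
    spec = spec.validate()
    rng = np.random.default_rng(spec.seed)
    p_na, p_an = spec.switch_rates

    rr: list[float] = []
    states: list[str] = []
    if spec.rhythm_class == "paroxysmal":
        # start from the stationary distribution of the two-state chain
        denom = p_na + p_an
        p_af0 = p_na / denom if denom > 0 else 0.0
        state = "af" if rng.random() < p_af0 else "normal"
    else:
        state = "af" if spec.rhythm_class == "af" else "normal"

    t = 0.0
    while t < spec.duration:
        if state == "af":
            mean, jit = (
                (spec.mean_rr, spec.rr_jitter)
                if spec.rhythm_class == "af"
                else (spec.af_mean_rr, spec.af_rr_jitter)
            )
            beat = _draw_af_rr(rng, mean, jit)
        else:
            beat = _draw_normal_rr(rng, spec.mean_rr, spec.rr_jitter, t)
        rr.append(beat)
        states.append(state)
        t += beat
        if spec.rhythm_class == "paroxysmal":
            if state == "normal" and rng.random() < p_na:
                state = "af"
            elif state == "af" and rng.random() < p_an:
                state = "normal"

    return RhythmRecording(
        rr=np.asarray(rr, dtype=float),
        ecg_id=f"{spec.rhythm_class}-{spec.seed}",
        diagnosis=DIAGNOSIS_OF_CLASS[spec.rhythm_class],
        states=np.asarray(states, dtype=object),
    )


# ---------------------------------------------------------------------------
# waveform rendering


def _gaussian_beat(t_rel: np.ndarray) -> np.ndarray:
    """Narrow Gaussian R-wave bump, 1 mV peak, ~12 ms half width."""
    return np.exp(-0.5 * (t_rel / 0.012) ** 2)


#: pluggable beat-template backends: name -> f(t_rel_seconds) -> mV
BEAT_TEMPLATES = {"gaussian": _gaussian_beat}

#: offset of the first R peak from the start of the rendered waveform (s)
FIRST_BEAT_OFFSET = 0.1


def render_waveform(
    recording: RhythmRecording, fs: float = 250.0, template: str = "gaussian"
) -> RhythmRecording:
    """Render a synthetic ECG-like waveform whose R-peak times follow ``rr``.

    Returns a copy of the recording with a ``(time_s, mv)`` waveform attached.
    The i-th and (i+1)-th rendered peaks are separated by ``rr[i]`` exactly
    (up to the sample grid), so peak detection on the output recovers the
    RR series.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    if recording.rr.size == 0:
        raise ValueError("cannot render a waveform from an empty RR series")
    beat_fn = BEAT_TEMPLATES[template]

    # peak i sits at offset + sum(rr[:i]); total span covers the last beat
    peak_times = FIRST_BEAT_OFFSET + np.concatenate([[0.0], np.cumsum(recording.rr[:-1])])
    t_end = peak_times[-1] + FIRST_BEAT_OFFSET
    t = np.arange(0.0, t_end, 1.0 / fs)
    mv = np.zeros_like(t)
    for pt in peak_times:
        lo = np.searchsorted(t, pt - 0.1)
        hi = np.searchsorted(t, pt + 0.1)
        mv[lo:hi] += beat_fn(t[lo:hi] - pt)

    out = dataclasses.replace(recording)
    out.waveform = np.column_stack([t, mv])
    out.fs = float(fs)
    return out


# ---------------------------------------------------------------------------
# abstract feature blobs


def simulate_feature_blobs(spec: BlobSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian mixture with unit within-cluster SD and separated centers.

    Centers are drawn isotropically and rescaled so the *minimum* pairwise
    center distance equals ``spec.separation``. Returns a feature table with
    columns ``f0..f{dim-1}`` plus ``ecg_id``/``snippet_index`` bookkeeping
    columns, and the true cluster labels.
    """
    spec = spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers = rng.normal(size=(spec.n_clusters, spec.dim))
    if spec.n_clusters > 1:
        from scipy.spatial.distance import pdist

        dmin = pdist(centers).min()
        while dmin == 0:  # pragma: no cover - measure-zero event
            centers = rng.normal(size=(spec.n_clusters, spec.dim))
            dmin = pdist(centers).min()
        centers *= spec.separation / dmin

    labels = np.repeat(np.arange(spec.n_clusters), spec.n_per_cluster)
    X = centers[labels] + rng.normal(size=(labels.size, spec.dim))
    table = pd.DataFrame(X, columns=[f"f{j}" for j in range(spec.dim)])
    table.insert(0, "ecg_id", [f"blob{lab}-{i}" for i, lab in enumerate(labels)])
    table.insert(1, "snippet_index", 0)
    return table, labels


# ---------------------------------------------------------------------------
# plain-text I/O


def write_rr_csv(recording: RhythmRecording, path) -> None:
    """Write the RR series as a two-column CSV (beat_index, rr_seconds)."""
    df = pd.DataFrame(
        {"beat_index": np.arange(recording.rr.size), "rr_seconds": recording.rr}
    )
    df.to_csv(path, index=False)


def read_rr_csv(path, ecg_id: str = "ecg", diagnosis: str | None = None) -> RhythmRecording:
    df = pd.read_csv(path)
    return RhythmRecording(
        rr=df["rr_seconds"].to_numpy(dtype=float), ecg_id=ecg_id, diagnosis=diagnosis
    )


def write_waveform_csv(recording: RhythmRecording, path) -> None:
    if recording.waveform is None:
        raise ValueError("recording has no rendered waveform")
    pd.DataFrame(recording.waveform, columns=["time_s", "mv"]).to_csv(path, index=False)
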