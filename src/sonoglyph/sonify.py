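"""Image-to-sound encoding: spectral-temporal mappings and WAV plumbing.

A square brightness image is rendered as a mono "soundscape": one image
axis indexes an oscillator bank of log-spaced frequencies (500–5000 Hz
over 64 steps by default), the other axis is scanned as time (64 steps of
1.05/64 s each, 1.05 s in total), and brightness sets oscillator amplitude.
A 3.3 ms onset click cues the start of the sonification.

Two presets mirror the mappings under study:

* **traditional** — pitch encodes elevation (low image rows = low
  frequencies, i.e. frequency increases bottom-to-top) and time encodes
  azimuth (left-to-right column scan).  This is the classic vOICe layout.
* **reversed** — pitch encodes azimuth (frequency increases left-to-right
  over columns) and time encodes elevation (top-to-bottom row scan).

A third, deliberately unstructured scheme assigns each stimulus one
constant pure tone drawn at random from the same 500–5000 Hz range, unique
per stimulus and separated from its nearest neighbour by at least 50 Hz.

Synthesis is strictly linear in pixel brightness: each active pixel
contributes one gated sinusoid atom (phase-continuous oscillator, phase 0
at sonification onset, raised-cosine gate edges), and the decoder in
:mod:`sonoglyph.decode` inverts exactly this dictionary.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .stimuli import PixelImage, as_pixel_image

__all__ = [
    "MappingSpec",
    "Soundscape",
    "ControlToneMap",
    "traditional_preset",
    "reversed_preset",
    "frequency_of_index",
    "make_click",
    "sonify",
    "assign_control_tones",
    "sonify_control",
    "write_wav",
    "read_wav",
    "activation_matrix",
    "image_from_activations",
]

_ROW_DIRECTIONS = ("top_to_bottom", "bottom_to_top")
_COL_DIRECTIONS = ("left_to_right", "right_to_left")


@dataclass(frozen=True)
class MappingSpec:
    """Configuration of one spectral-temporal mapping.

    Parameters
    ----------
    freq_axis : {"rows", "cols"}
        Which image axis indexes the oscillator bank.
    freq_direction : str
        Image direction of increasing frequency ("bottom_to_top" /
        "top_to_bottom" for rows, "left_to_right" / "right_to_left" for
        columns).
    scan_direction : str
        Image direction of advancing time along the other axis.
    f_min, f_max : float
        Frequency range in Hz; endpoints are attained exactly at the first
        and last frequency steps.
    n_steps : int
        Steps per axis (square images of this size are sonified).
    column_duration : float
        Seconds per time step; default 1.05/64 s so the total sonification
        lasts exactly 1.05 s.
    sample_rate : float
        Output sample rate in Hz.
    click_duration : float
        Onset-click length in seconds (0 disables the click).
    click_frequency, click_amplitude : float
        Carrier and peak level of the raised-cosine click burst.
    ramp_duration : float
        Raised-cosine gate-edge ramp in seconds; 0 gives hard rectangular
        gates (the analytically exact mode).
    peak : float
        Peak-normalisation target for the sonification span.
    """

    freq_axis: str = "rows"
    freq_direction: str = "bottom_to_top"
    scan_direction: str = "left_to_right"
    f_min: float = 500.0
    f_max: float = 5000.0
    n_steps: int = 64
    column_duration: float = 1.05 / 64
    sample_rate: float = 44100.0
    click_duration: float = 0.0033
    click_frequency: float = 2500.0
    click_amplitude: float = 0.9
    ramp_duration: float = 0.001
    peak: float = 0.9

    def __post_init__(self):
        if self.freq_axis not in ("rows", "cols"):
            raise ValueError(f"freq_axis must be 'rows' or 'cols', got {self.freq_axis!r}")
        freq_dirs = _ROW_DIRECTIONS if self.freq_axis == "rows" else _COL_DIRECTIONS
        scan_dirs = _COL_DIRECTIONS if self.freq_axis == "rows" else _ROW_DIRECTIONS
        if self.freq_direction not in freq_dirs:
            raise ValueError(
                f"freq_direction {self.freq_direction!r} invalid for freq_axis "
                f"{self.freq_axis!r}; expected one of {freq_dirs}"
            )
        if self.scan_direction not in scan_dirs:
            raise ValueError(
                f"scan_direction {self.scan_direction!r} invalid for time axis; "
                f"expected one of {scan_dirs}"
            )
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if self.f_max >= self.sample_rate / 2:
            raise ValueError("f_max must lie below the Nyquist frequency")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.column_duration <= 0:
            raise ValueError("column_duration must be positive")

    @property
    def time_axis(self) -> str:
        return "cols" if self.freq_axis == "rows" else "rows"

    @property
    def total_duration(self) -> float:
        """Sonification duration in seconds (click excluded)."""
        return self.n_steps * self.column_duration

    def step_boundaries(self) -> np.ndarray:
        """Cumulative-rounded sample index of each time-step boundary."""
        edges = np.arange(self.n_steps + 1) * self.column_duration * self.sample_rate
        return np.round(edges).astype(int)

    def exact(self) -> "MappingSpec":
        """Copy with hard gates (no edge ramps) for analytic exactness."""
        return replace(self, ramp_duration=0.0)


def traditional_preset(**overrides) -> MappingSpec:
    """Classic layout: pitch = elevation (bottom = 500 Hz), time = azimuth."""
    return MappingSpec(
        freq_axis="rows",
        freq_direction="bottom_to_top",
        scan_direction="left_to_right",
        **overrides,
    )


def reversed_preset(**overrides) -> MappingSpec:
    """Swapped layout: pitch = azimuth (left = 500 Hz), time = elevation."""
    return MappingSpec(
        freq_axis="cols",
        freq_direction="left_to_right",
        scan_direction="top_to_bottom",
        **overrides,
    )


def frequency_of_index(i, spec: MappingSpec):
    """Frequency in Hz of oscillator step ``i``: geometric interpolation.

    f(i) = f_min * (f_max/f_min)^(i/(n-1)), so log-frequency is affine in
    the step index and both endpoints are attained exactly.
    """
    idx = np.asarray(i)
    if np.any(idx < 0) or np.any(idx > spec.n_steps - 1):
        raise ValueError(f"step index out of range 0..{spec.n_steps - 1}")
    ratio = spec.f_max / spec.f_min
    return spec.f_min * ratio ** (idx / (spec.n_steps - 1))


@dataclass(frozen=True)
class Soundscape:
    """A mono waveform plus segment markers for the click and sonification."""

    samples: np.ndarray
    sample_rate: float
    click_span: tuple[int, int]
    sonification_span: tuple[int, int]
    source_id: str | None = None

    @property
    def click_samples(self) -> np.ndarray:
        return self.samples[self.click_span[0] : self.click_span[1]]

    @property
    def sonification_samples(self) -> np.ndarray:
        return self.samples[self.sonification_span[0] : self.sonification_span[1]]

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def make_click(spec: MappingSpec) -> np.ndarray:
    """Deterministic onset click: a raised-cosine-windowed tone burst."""
    n = int(round(spec.click_duration * spec.sample_rate))
    if n <= 0:
        return np.zeros(0)
    t = np.arange(n) / spec.sample_rate
    window = 0.5 - 0.5 * np.cos(2 * np.pi * (np.arange(n) + 0.5) / n)
    return spec.click_amplitude * window * np.sin(2 * np.pi * spec.click_frequency * t)


def _gate_window(length: int, ramp_samples: int) -> np.ndarray:
    """Unit gate with raised-cosine edges confined inside the gate span."""
    w = np.ones(length)
    r = min(ramp_samples, length // 2)
    if r > 0:
        edge = 0.5 - 0.5 * np.cos(np.pi * (np.arange(r) + 0.5) / r)
        w[:r] = edge
        w[-r:] = edge[::-1]
    return w


def activation_matrix(image: PixelImage, spec: MappingSpec) -> np.ndarray:
    """Map image pixels to oscillator activations A[freq_step, time_step].

    Frequency step 0 is the lowest frequency; time step 0 is the first.
    """
    img = as_pixel_image(image, size=spec.n_steps)
    mat = img if spec.freq_axis == "rows" else img.T
    if spec.freq_direction in ("bottom_to_top", "right_to_left"):
        mat = mat[::-1, :]
    if spec.scan_direction in ("bottom_to_top", "right_to_left"):
        mat = mat[:, ::-1]
    return np.ascontiguousarray(mat)


def image_from_activations(act: np.ndarray, spec: MappingSpec) -> PixelImage:
    """Inverse of :func:`activation_matrix`: activations back to image pixels."""
    mat = np.asarray(act, dtype=float)
    if mat.shape != (spec.n_steps, spec.n_steps):
        raise ValueError(f"activation matrix must be {spec.n_steps}x{spec.n_steps}")
    if spec.scan_direction in ("bottom_to_top", "right_to_left"):
        mat = mat[:, ::-1]
    if spec.freq_direction in ("bottom_to_top", "right_to_left"):
        mat = mat[::-1, :]
    return np.ascontiguousarray(mat if spec.freq_axis == "rows" else mat.T)


def _synthesize(act: np.ndarray, spec: MappingSpec) -> np.ndarray:
    """Raw (pre-normalisation) additive synthesis of an activation matrix."""
    bounds = spec.step_boundaries()
    total = bounds[-1]
    out = np.zeros(total)
    freqs = np.asarray(frequency_of_index(np.arange(spec.n_steps), spec))
    ramp = int(round(spec.ramp_duration * spec.sample_rate))
    t = np.arange(total) / spec.sample_rate
    for c in range(spec.n_steps):
        amps = act[:, c]
        active = np.nonzero(amps > 0)[0]
        if active.size == 0:
            continue
        s0, s1 = bounds[c], bounds[c + 1]
        # phase-continuous: oscillator phase is 2*pi*f*t from onset, not gate start
        seg = np.sin(2 * np.pi * np.outer(freqs[active], t[s0:s1]))
        mixed = amps[active] @ seg
        out[s0:s1] = mixed * _gate_window(s1 - s0, ramp)
    return out


def sonify(image: PixelImage, spec: MappingSpec, *, source_id: str | None = None) -> Soundscape:
    """Render an image as a click-prefixed mono soundscape.

    Each pixel with brightness b > 0 contributes a sinusoid at its
    frequency step, gated to its time step, with amplitude proportional to
    b.  The summed sonification is peak-normalised to ``spec.peak``
    (silence stays silent) and the onset click is prepended at t = 0.
    """
    act = activation_matrix(image, spec)
    son = _synthesize(act, spec)
    peak = np.abs(son).max() if son.size else 0.0
    if peak > 0:
        son = son * (spec.peak / peak)
    click = make_click(spec)
    samples = np.concatenate([click, son])
    return Soundscape(
        samples=samples,
        sample_rate=spec.sample_rate,
        click_span=(0, len(click)),
        sonification_span=(len(click), len(samples)),
        source_id=source_id,
    )


@dataclass(frozen=True)
class ControlToneMap:
    """Arbitrary stimulus -> constant-frequency assignment (control scheme)."""

    tones: dict[str, float]
    seed: int
    min_separation: float = 50.0

    def frequency(self, stimulus_id: str) -> float:
        try:
            return self.tones[stimulus_id]
        except KeyError:
            raise KeyError(f"no control tone assigned to {stimulus_id!r}") from None


def assign_control_tones(
    stimulus_ids,
    spec: MappingSpec,
    *,
    min_separation: float = 50.0,
    seed: int = 0,
) -> ControlToneMap:
    """Assign each stimulus a unique random tone, neighbours >= 50 Hz apart.

    Uses the order-statistics construction: draw ``k`` points uniformly in
    the separation-reduced interval, sort them, then add ``i * sep`` —
    uniform over the feasible set with the separation guaranteed by
    construction.  The assignment of sorted tones to ids is a seeded random
    permutation.
    """
    ids = list(stimulus_ids)
    k = len(ids)
    if len(set(ids)) != k:
        raise ValueError("stimulus ids must be unique")
    span = spec.f_max - spec.f_min
    needed = (k - 1) * min_separation
    if k >= 1 and needed > span:
        cap = int(span // min_separation) + 1
        raise ValueError(
            f"cannot place {k} tones with {min_separation} Hz separation in "
            f"[{spec.f_min}, {spec.f_max}] Hz (capacity {cap})"
        )
    rng = np.random.default_rng(seed)
    base = np.sort(rng.uniform(0.0, span - needed, size=k))
    freqs = spec.f_min + base + min_separation * np.arange(k)
    order = rng.permutation(k)
    tones = {ids[i]: float(freqs[order[i]]) for i in range(k)}
    return ControlToneMap(tones=tones, seed=seed, min_separation=min_separation)


def sonify_control(
    stimulus_id: str, tone_map: ControlToneMap, spec: MappingSpec
) -> Soundscape:
    """Render a stimulus under the control scheme: click + one constant tone."""
    f = tone_map.frequency(stimulus_id)
    bounds = spec.step_boundaries()
    total = bounds[-1]
    t = np.arange(total) / spec.sample_rate
    ramp = int(round(spec.ramp_duration * spec.sample_rate))
    tone = spec.peak * np.sin(2 * np.pi * f * t) * _gate_window(total, ramp)
    click = make_click(spec)
    samples = np.concatenate([click, tone])
    return Soundscape(
        samples=samples,
        sample_rate=spec.sample_rate,
        click_span=(0, len(click)),
        sonification_span=(len(click), len(samples)),
        source_id=stimulus_id,
    )


def write_wav(soundscape: Soundscape, path) -> None:
    """Write a soundscape as 16-bit PCM mono WAV."""
    samples = np.asarray(soundscape.samples, dtype=float)
    if samples.size and np.abs(samples).max() > 1.0:
        raise ValueError("samples exceed [-1, 1]; normalise before writing")
    data = np.round(samples * 32767.0).astype("<i2")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(int(round(soundscape.sample_rate)))
        wf.writeframes(data.tobytes())


def read_wav(path, spec: MappingSpec | None = None, *, source_id: str | None = None) -> Soundscape:
    """Read a 16-bit PCM mono WAV back into a Soundscape.

    WAV files carry no segment markers; when ``spec`` is given, the click
    span is reconstructed from its click duration, otherwise the whole file
    is treated as sonification.
    """
    with wave.open(str(path), "rb") as wf:
        if wf.getnchannels() != 1 or wf.getsampwidth() != 2:
            raise ValueError(f"{path}: expected 16-bit mono PCM WAV")
        rate = float(wf.getframerate())
        raw = wf.readframes(wf.getnframes())
    samples = np.frombuffer(raw, dtype="<i2").astype(float) / 32767.0
    n_click = int(round(spec.click_duration * spec.sample_rate)) if spec else 0
    n_click = min(n_click, len(samples))
    return Soundscape(
        samples=samples,
        sample_rate=rate,
        click_span=(0, n_click),
        sonification_span=(n_click, len(samples)),
        source_id=source_id,
    )


def mapping_to_dict(spec: MappingSpec) -> dict:
    """Serialise a MappingSpec to plain JSON-compatible fields."""
    return {
        "freq_axis": spec.freq_axis,
        "freq_direction": spec.freq_direction,
        "scan_direction": spec.scan_direction,
        "f_min": spec.f_min,
        "f_max": spec.f_max,
        "n_steps": spec.n_steps,
        "column_duration": spec.column_duration,
        "sample_rate": spec.sample_rate,
        "click_duration": spec.click_duration,
        "click_frequency": spec.click_frequency,
        "click_amplitude": spec.click_amplitude,
        "ramp_duration": spec.ramp_duration,
        "peak": spec.peak,
    }


def mapping_from_dict(fields: dict) -> MappingSpec:
    return MappingSpec(**fields)
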