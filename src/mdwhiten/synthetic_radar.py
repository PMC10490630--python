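"""Synthetic FMCW micro-Doppler signature simulation.

Simulates the complex-baseband return of a frequency-modulated
continuous-wave (FMCW) radar observing a human modelled as a small set of
moving point scatterers, and converts it into labeled 75x75 grayscale
micro-Doppler signature images:

1. **Baseband superposition** — each scatterer *i* with two-way delay
   ``tau_i(t)`` and Doppler ``fD_i(t)`` contributes
   ``A_i exp(j 2 pi ((fD_i - alpha tau_i) t_fast - fc tau_i))``; delays and
   Dopplers are held constant within one chirp and updated per chirp
   (stop-and-hop convention).
2. **Range map** — a normalized DFT along fast time turns the beat
   frequency ``alpha tau`` into a range-bin index.
3. **Range-bin summation** — the bins spanning the subject are summed into
   a single slow-time signal.
4. **Spectrogram** — the squared-magnitude STFT of that signal (Hann
   window 256, hop 2, 2048-point DFT by default) is the micro-Doppler
   signature; it is log-scaled, cropped, downscaled to 75x75 and quantized
   to 0..255.

Six activity templates (walking, sitting down, standing up, bending,
drinking, falling) produce the distinct signature morphologies of this
sensing problem: periodic limb oscillations for walking, short one-sided or
biphasic transients for the sedentary activities, and a fast broadband
excursion for falling.  A population of simulated subjects with per-subject
kinematic perturbations reproduces the dataset geometry used downstream
(95 signatures per class from 33 subjects with 2-3 repetitions each).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
from PIL import Image
from scipy.signal.windows import hann

from .whitening import ValidationError

C_LIGHT = 299_792_458.0

#: activity classes, in label order
CLASSES = (
    "walking",
    "sitting_down",
    "standing_up",
    "bending",
    "drinking",
    "falling",
)


# ---------------------------------------------------------------------------
# radar and spectrogram parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadarParams:
    """FMCW waveform and sampling grid.

    Defaults follow a 5.8 GHz radar with 400 MHz sweep bandwidth, 1 ms
    chirps and 128 fast-time samples per chirp; ``num_chirps`` chirps at the
    1 kHz chirp repetition frequency set the slow-time span.
    """

    carrier_frequency: float = 5.8e9
    bandwidth: float = 400e6
    chirp_duration: float = 1e-3
    samples_per_chirp: int = 128
    num_chirps: int = 2400

    def __post_init__(self):
        if self.bandwidth <= 0 or self.chirp_duration <= 0:
            raise ValidationError("bandwidth and chirp duration must be positive")
        if self.samples_per_chirp < 2 or self.num_chirps < 2:
            raise ValidationError("need at least 2 fast-time and 2 slow-time samples")

    @property
    def chirp_rate(self) -> float:
        """Sweep slope alpha = bandwidth / chirp duration [Hz/s]."""
        return self.bandwidth / self.chirp_duration

    @property
    def fast_time_sample_rate(self) -> float:
        return self.samples_per_chirp / self.chirp_duration

    @property
    def slow_time(self) -> np.ndarray:
        return np.arange(self.num_chirps) * self.chirp_duration

    @property
    def fast_time(self) -> np.ndarray:
        return np.arange(self.samples_per_chirp) / self.fast_time_sample_rate

    def beat_bin(self, r: float | np.ndarray):
        """Fractional range-bin coordinate of a target at range ``r``.

        The baseband convention used here (negative beat frequency
        ``-alpha tau`` against the forward-DFT kernel) places a target at
        the aliased bin ``N1 - 2 B r / c`` (mod N1).
        """
        b = 2.0 * self.bandwidth * np.asarray(r, dtype=float) / C_LIGHT
        return (-b) % self.samples_per_chirp


@dataclass
class SpectrogramParams:
    """STFT analysis parameters for the micro-Doppler signature."""

    window: np.ndarray = field(default_factory=lambda: hann(256, sym=False))
    hop: int = 2
    dft_size: int = 2048
    range_bin_lo: int | None = None  # None: span the scatterer extent
    range_bin_hi: int | None = None

    def __post_init__(self):
        self.window = np.asarray(self.window, dtype=float)
        if self.hop < 1:
            raise ValidationError("hop must be >= 1")
        if self.dft_size < len(self.window):
            raise ValidationError("dft_size must be >= window length")


# ---------------------------------------------------------------------------
# scatterers and activity templates
# ---------------------------------------------------------------------------


@dataclass
class Scatterer:
    """A point reflector with slow-time range and amplitude trajectories.

    ``range_fn`` maps a slow-time vector [s] to range [m] (> 0);
    ``amplitude_fn`` maps it to a non-negative reflectivity.  The two-way
    delay is ``2 r / c`` and the Doppler trajectory is
    ``-2 fc (dr/dt) / c``, evaluated numerically from the sampled range.
    """

    range_fn: callable
    amplitude_fn: callable = staticmethod(lambda t: np.ones_like(t))

    def sample(self, t: np.ndarray, fc: float):
        r = np.broadcast_to(
            np.asarray(self.range_fn(t), dtype=float), t.shape
        ).astype(float)
        a = np.broadcast_to(np.asarray(self.amplitude_fn(t), dtype=float), t.shape)
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(a))):
            raise ValidationError("scatterer trajectory contains non-finite values")
        if np.any(r <= 0):
            raise ValidationError("scatterer range must stay positive")
        if np.any(a < 0):
            raise ValidationError("scatterer amplitude must be non-negative")
        tau = 2.0 * r / C_LIGHT
        doppler = -2.0 * fc * np.gradient(r, t) / C_LIGHT
        return a, r, tau, doppler


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class SubjectProfile:
    """Per-subject kinematic perturbations, drawn once per simulated subject."""

    speed_scale: float = 1.0
    amplitude_scale: float = 1.0
    base_range: float = 3.0
    start_offset: float = 0.6


@dataclass
class ActivityTemplate:
    """One activity class: a constructor of scatterers given a subject profile.

    ``builder(profile, rng)`` returns the scatterer list; ``rng`` supplies
    repetition-level jitter (start-time and phase variation within a
    subject).
    """

    class_label: str
    builder: callable
    duration: float = 2.4

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError("duration must be positive")

    def scatterers(self, profile: SubjectProfile, rng: np.random.Generator):
        scats = self.builder(profile, rng)
        if not scats:
            raise ValidationError("template produced no scatterers")
        return scats


def _walking(p: SubjectProfile, rng) -> list:
    v = 1.0 * p.speed_scale * rng.uniform(0.92, 1.08)
    f_step = 1.8 * p.speed_scale * rng.uniform(0.95, 1.05)
    # start one dwell upstream of the base range so the closest approach
    # stays positive for every perturbation in the configured ranges
    r0 = p.base_range + v * 2.4
    phase = rng.uniform(0, 2 * np.pi)
    torso = Scatterer(
        lambda t: r0 - v * t + 0.02 * np.sin(2 * np.pi * 2 * f_step * t + phase),
        _const_amp(rng.lognormal(0.0, 0.25)),
    )
    limbs = []
    for amp, ph, a_lvl in (
        (0.25, 0.0, 0.45),
        (0.25, np.pi, 0.45),
        (0.12, np.pi / 2, 0.25),
        (0.12, 3 * np.pi / 2, 0.25),
    ):
        amp = amp * p.amplitude_scale * rng.uniform(0.8, 1.2)
        a_lvl = a_lvl * rng.lognormal(0.0, 0.3)
        limbs.append(
            Scatterer(
                lambda t, amp=amp, ph=ph: r0 - v * t
                + amp * np.sin(2 * np.pi * f_step * t + ph + phase),
                _const_amp(a_lvl),
            )
        )
    return [torso] + limbs


def _const_amp(level):
    return lambda t, level=level: np.full_like(t, level)


def _transient(p, rng, disp, width, biphasic=False, head_factor=1.3):
    """Torso+head transient common to the sedentary activities.

    ``disp`` > 0 moves away from the radar; a biphasic transient goes out
    and back (half-sine) instead of settling (smoothstep).  Displacement,
    duration and reflectivities carry repetition-level jitter, so the
    transient classes overlap the way repeated human motions do.
    """
    t0 = p.start_offset + rng.uniform(-0.15, 0.15)
    w = width / p.speed_scale * rng.uniform(0.7, 1.4)
    d = disp * p.amplitude_scale * rng.uniform(0.6, 1.4)

    def motion(t, scale):
        x = (t - t0) / w
        if biphasic:
            return scale * np.sin(np.pi * np.clip(x, 0.0, 1.0))
        return scale * _smoothstep(x)

    torso = Scatterer(lambda t: p.base_range + motion(t, d),
                      _const_amp(rng.lognormal(0.0, 0.25)))
    head = Scatterer(lambda t: p.base_range - 0.1 + motion(t, d * head_factor),
                     _const_amp(0.5 * rng.lognormal(0.0, 0.3)))
    static = Scatterer(lambda t: p.base_range + 0.15,
                       _const_amp(0.35 * rng.lognormal(0.0, 0.3)))
    return [torso, head, static]


def _sitting(p, rng):
    return _transient(p, rng, disp=+0.35, width=0.9)


def _standing(p, rng):
    # rising mirrors sitting down: the torso moves toward the radar and
    # settles, giving the opposite-sign Doppler transient
    return _transient(p, rng, disp=-0.35, width=0.9)


def _bending(p, rng):
    return _transient(p, rng, disp=-0.30, width=1.2, biphasic=True)


def _drinking(p, rng):
    t0 = p.start_offset + rng.uniform(-0.15, 0.15)
    w = 1.1 / p.speed_scale * rng.uniform(0.7, 1.4)
    d = 0.16 * p.amplitude_scale * rng.uniform(0.6, 1.4)
    hand = Scatterer(
        lambda t: p.base_range - d * np.sin(np.pi * np.clip((t - t0) / w, 0.0, 1.0)),
        _const_amp(0.5 * rng.lognormal(0.0, 0.3)),
    )
    torso = Scatterer(lambda t: p.base_range + 0.1,
                      _const_amp(rng.lognormal(0.0, 0.25)))
    return [hand, torso]


def _falling(p, rng):
    t0 = p.start_offset + rng.uniform(-0.15, 0.15)
    w = 0.45 / p.speed_scale * rng.uniform(0.85, 1.2)
    amp = p.amplitude_scale * rng.uniform(0.8, 1.2)
    torso = Scatterer(
        lambda t: p.base_range + 0.9 * amp * _smoothstep((t - t0) / w),
        _const_amp(rng.lognormal(0.0, 0.25)),
    )
    head = Scatterer(
        lambda t: p.base_range - 0.15
        + 1.2 * amp * _smoothstep((t - t0) / (0.85 * w)),
        _const_amp(0.6 * rng.lognormal(0.0, 0.3)),
    )
    legs = Scatterer(
        lambda t: p.base_range + 0.1
        + 0.4 * amp * _smoothstep((t - t0 - 0.1 * w) / w),
        _const_amp(0.4 * rng.lognormal(0.0, 0.3)),
    )
    return [torso, head, legs]


def default_templates() -> list[ActivityTemplate]:
    builders = {
        "walking": _walking,
        "sitting_down": _sitting,
        "standing_up": _standing,
        "bending": _bending,
        "drinking": _drinking,
        "falling": _falling,
    }
    return [ActivityTemplate(c, builders[c]) for c in CLASSES]


# ---------------------------------------------------------------------------
# signal chain
# ---------------------------------------------------------------------------


def simulate_baseband(scatterers: list, params: RadarParams) -> np.ndarray:
    """Superpose complex-baseband returns on the fast-time x slow-time grid.

    Delay and Doppler of every scatterer are evaluated once per chirp
    (stop-and-hop); within chirp ``n2`` the contribution is
    ``A exp(j 2 pi ((fD - alpha tau) t1 - fc tau))``.  An empty scatterer
    list yields the all-zero matrix.
    """
    t1 = params.fast_time[:, None]
    t2 = params.slow_time
    s = np.zeros((params.samples_per_chirp, params.num_chirps), dtype=complex)
    for sc in scatterers:
        a, _, tau, doppler = sc.sample(t2, params.carrier_frequency)
        freq = doppler - params.chirp_rate * tau
        s += a * np.exp(2j * np.pi * (freq[None, :] * t1 - params.carrier_frequency * tau[None, :]))
    return s


@dataclass
class RangeMap:
    """Fast-time DFT of the baseband matrix: range bins x slow time."""

    values: np.ndarray
    bin_to_range: float  # meters per (un-aliased) beat bin

    @property
    def shape(self):
        return self.values.shape


def compute_range_map(s: np.ndarray, params: RadarParams) -> RangeMap:
    """Normalized DFT along fast time: ``R(p,.) = (1/N1) sum s e^{-j2pi p n1/N1}``."""
    s = np.asarray(s)
    if s.shape != (params.samples_per_chirp, params.num_chirps):
        raise ValidationError(
            f"baseband shape {s.shape} does not match params "
            f"({params.samples_per_chirp}, {params.num_chirps})"
        )
    values = np.fft.fft(s, axis=0) / params.samples_per_chirp
    return RangeMap(values=values, bin_to_range=C_LIGHT / (2.0 * params.bandwidth))


def sum_range_bins(R: RangeMap | np.ndarray, p1: int, p2: int) -> np.ndarray:
    """Sum range bins ``p1..p2`` (inclusive) into one slow-time signal."""
    values = R.values if isinstance(R, RangeMap) else np.asarray(R)
    n_bins = values.shape[0]
    if not (0 <= p1 <= p2 < n_bins):
        raise ValidationError(f"need 0 <= p1 <= p2 < {n_bins}, got ({p1}, {p2})")
    return values[p1 : p2 + 1].sum(axis=0)


def compute_spectrogram(v: np.ndarray, sp: SpectrogramParams) -> np.ndarray:
    """Squared-magnitude STFT of the slow-time signal.

    Returns ``D`` of shape (frames, dft_size): frame ``k1`` covers samples
    ``k1*hop .. k1*hop + N - 1`` (only full windows are taken) and the
    Doppler axis is DFT-shifted so zero Doppler sits at the center column.
    """
    v = np.asarray(v)
    N = len(sp.window)
    if len(v) < N:
        raise ValidationError("signal shorter than the analysis window")
    frames = np.lib.stride_tricks.sliding_window_view(v, N)[:: sp.hop]
    spec = np.fft.fft(frames * sp.window, n=sp.dft_size, axis=1)
    return np.fft.fftshift(np.abs(spec) ** 2, axes=1)


def spectrogram_frequencies(sp: SpectrogramParams, prf: float) -> np.ndarray:
    """Doppler frequency [Hz] of each (shifted) spectrogram column."""
    return np.fft.fftshift(np.fft.fftfreq(sp.dft_size, d=1.0 / prf))


@dataclass
class MicroDopplerSignature:
    """A 75x75 grayscale micro-Doppler image with its labels."""

    image: np.ndarray  # uint8, (75, 75); rows = Doppler (positive up), cols = time
    class_label: str = ""
    subject_id: int = -1
    repetition_id: int = -1

    @property
    def label_index(self) -> int:
        return CLASSES.index(self.class_label)


def export_signature(
    D: np.ndarray,
    crop: tuple | None = None,
    out_size: tuple = (75, 75),
    dynamic_range_db: float = 40.0,
    class_label: str = "",
    subject_id: int = -1,
    repetition_id: int = -1,
) -> MicroDopplerSignature:
    """Map a spectrogram to the stored grayscale-image format.

    Log-power mapping (clipped ``dynamic_range_db`` below the peak), crop to
    ``crop = (frame_lo, frame_hi, bin_lo, bin_hi)`` (half-open, in the
    (frames, dft) layout of :func:`compute_spectrogram`), orientation flip
    so time runs horizontally and positive Doppler points up, bilinear
    downscale to ``out_size``, then a linear stretch to integers 0..255 (a
    constant image maps to all zeros).
    """
    D = np.asarray(D, dtype=float)
    if D.size == 0:
        raise ValidationError("empty spectrogram")
    if crop is not None:
        f0, f1, b0, b1 = crop
        D = D[f0:f1, b0:b1]
        if D.size == 0:
            raise ValidationError("crop produced an empty region")
    peak = D.max()
    floor = peak * 10.0 ** (-dynamic_range_db / 10.0) if peak > 0 else 1.0
    db = 10.0 * np.log10(np.maximum(D, floor) + np.finfo(float).tiny)
    img = db.T[::-1]  # rows: Doppler, high frequencies on top; cols: time
    resized = np.asarray(
        Image.fromarray(img.astype(np.float32)).resize(
            (out_size[1], out_size[0]), Image.BILINEAR
        ),
        dtype=float,
    )
    lo, hi = resized.min(), resized.max()
    if hi > lo:
        pixels = np.rint((resized - lo) / (hi - lo) * 255.0)
    else:
        pixels = np.zeros_like(resized)
    return MicroDopplerSignature(
        image=pixels.astype(np.uint8),
        class_label=class_label,
        subject_id=subject_id,
        repetition_id=repetition_id,
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def _auto_range_bins(scatterers, params: RadarParams):
    """Range-bin window spanning the scatterer extent plus one guard bin."""
    t2 = params.slow_time
    rs = np.concatenate([np.atleast_1d(sc.range_fn(t2)) for sc in scatterers])
    bins = params.beat_bin(np.array([rs.max(), rs.min()]))
    p1 = max(int(np.floor(bins.min())) - 1, 0)
    p2 = min(int(np.ceil(bins.max())) + 1, params.samples_per_chirp - 1)
    return p1, p2


def render_signature(
    scatterers,
    params: RadarParams,
    sp: SpectrogramParams,
    doppler_crop_hz: float = 200.0,
    snr_db: float | None = None,
    noise_rng: np.random.Generator | None = None,
    **labels,
) -> MicroDopplerSignature:
    """Run the full signal chain for one scatterer set."""
    s = simulate_baseband(scatterers, params)
    if snr_db is not None:
        power = np.mean(np.abs(s) ** 2)
        sigma = np.sqrt(power * 10.0 ** (-snr_db / 10.0) / 2.0)
        rng = noise_rng if noise_rng is not None else np.random.default_rng(0)
        s = s + sigma * (rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape))
    R = compute_range_map(s, params)
    p1, p2 = sp.range_bin_lo, sp.range_bin_hi
    if p1 is None or p2 is None:
        p1, p2 = _auto_range_bins(scatterers, params)
    v = sum_range_bins(R, p1, p2)
    D = compute_spectrogram(v, sp)
    freqs = spectrogram_frequencies(sp, 1.0 / params.chirp_duration)
    keep = np.flatnonzero(np.abs(freqs) <= doppler_crop_hz)
    crop = (0, D.shape[0], int(keep[0]), int(keep[-1]) + 1)
    return export_signature(D, crop=crop, **labels)


@dataclass
class DatasetConfig:
    """Study-condition defaults for the synthetic population."""

    n_subjects: int = 33
    signatures_per_class: int = 95
    radar: RadarParams = field(default_factory=RadarParams)
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    doppler_crop_hz: float = 200.0
    snr_db: float = -8.0
    # per-subject perturbation ranges
    speed_range: tuple = (0.7, 1.3)
    amplitude_range: tuple = (0.4, 1.6)
    base_range_m: tuple = (1.5, 4.0)
    start_offset_s: tuple = (0.2, 1.4)


def generate_dataset(
    templates: list[ActivityTemplate] | None = None,
    config: DatasetConfig | None = None,
    seed: int = 0,
) -> list[MicroDopplerSignature]:
    """Generate the labeled synthetic signature population.

    Deterministic given ``seed``.  Subject kinematics are drawn once per
    subject and shared across that subject's repetitions and classes;
    repetition-level jitter (start time, phases, noise) varies per
    recording.  Subjects repeat each activity 2 or 3 times, with the number
    of 3-repetition subjects chosen so every class has exactly
    ``signatures_per_class`` signatures.
    """
    cfg = config or DatasetConfig()
    templates = templates if templates is not None else default_templates()
    if cfg.n_subjects < 1:
        raise ValidationError("need at least one subject")
    n3 = cfg.signatures_per_class - 2 * cfg.n_subjects
    if not 0 <= n3 <= cfg.n_subjects:
        raise ValidationError(
            "signatures_per_class incompatible with 2-3 repetitions per subject"
        )
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(cfg.n_subjects)
    signatures = []
    for sid in range(cfg.n_subjects):
        srng = np.random.default_rng(subject_seeds[sid])
        profile = SubjectProfile(
            speed_scale=srng.uniform(*cfg.speed_range),
            amplitude_scale=srng.uniform(*cfg.amplitude_range),
            base_range=srng.uniform(*cfg.base_range_m),
            start_offset=srng.uniform(*cfg.start_offset_s),
        )
        reps = 3 if sid < n3 else 2
        for tpl in templates:
            for rep in range(reps):
                rep_rng = np.random.default_rng(srng.integers(2**31))
                scats = tpl.scatterers(profile, rep_rng)
                signatures.append(
                    render_signature(
                        scats,
                        cfg.radar,
                        cfg.spectrogram,
                        doppler_crop_hz=cfg.doppler_crop_hz,
                        snr_db=cfg.snr_db,
                        noise_rng=rep_rng,
                        class_label=tpl.class_label,
                        subject_id=sid,
                        repetition_id=rep,
                    )
                )
    return signatures


# ---------------------------------------------------------------------------
# dataset containers and I/O
# ---------------------------------------------------------------------------


@dataclass
class SignatureDataset:
    """Array-of-images container used by the training pipeline.

    ``images`` is uint8 of shape (n, 75, 75); ``labels`` are integer class
    indices into ``class_names``; ``subjects`` and ``repetitions`` carry the
    per-signature provenance needed for subject-wise splitting.
    """

    images: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    repetitions: np.ndarray
    class_names: tuple = CLASSES

    def __len__(self):
        return len(self.images)

    def subset(self, idx) -> "SignatureDataset":
        return SignatureDataset(
            self.images[idx], self.labels[idx], self.subjects[idx],
            self.repetitions[idx], self.class_names,
        )

    @classmethod
    def from_signatures(cls, signatures: list) -> "SignatureDataset":
        return cls(
            images=np.stack([s.image for s in signatures]),
            labels=np.array([s.label_index for s in signatures]),
            subjects=np.array([s.subject_id for s in signatures]),
            repetitions=np.array([s.repetition_id for s in signatures]),
        )


def save_dataset_h5(dataset: SignatureDataset, path: str):
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=dataset.images, dtype="uint8")
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset("subjects", data=dataset.subjects)
        f.create_dataset("repetitions", data=dataset.repetitions)
        f.attrs["class_names"] = list(dataset.class_names)


def save_dataset_png(dataset: SignatureDataset, out_dir: str):
    """One 8-bit grayscale PNG per signature plus a CSV manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(len(dataset)):
        name = (
            f"{dataset.class_names[dataset.labels[i]]}"
            f"_s{dataset.subjects[i]:03d}_r{dataset.repetitions[i]}.png"
        )
        Image.fromarray(dataset.images[i], mode="L").save(os.path.join(out_dir, name))
        rows.append((name, dataset.class_names[dataset.labels[i]],
                     int(dataset.subjects[i]), int(dataset.repetitions[i])))
    with open(os.path.join(out_dir, "manifest.csv"), "w", newline="") as f:
        wr = csv.writer(f)
        wr.writerow(["path", "class_label", "subject_id", "repetition_id"])
        wr.writerows(rows)


def load_dataset(path: str) -> SignatureDataset:
    """Load signatures from an HDF5 container or a PNG directory + manifest.

    Any user-supplied collection of 75x75 grayscale images (e.g. a measured
    dataset) in either layout is accepted.
    """
    if os.path.isdir(path):
        manifest = os.path.join(path, "manifest.csv")
        if not os.path.exists(manifest):
            raise ValidationError(f"no manifest.csv in {path}")
        images, labels, subjects, reps = [], [], [], []
        names: list = []
        with open(manifest, newline="") as f:
            for row in csv.DictReader(f):
                img = np.asarray(
                    Image.open(os.path.join(path, row["path"])).convert("L")
                )
                if img.shape != (75, 75):
                    raise ValidationError(
                        f"{row['path']}: expected a 75x75 image, got {img.shape}"
                    )
                images.append(img)
                if row["class_label"] not in names:
                    names.append(row["class_label"])
                labels.append(names.index(row["class_label"]))
                subjects.append(int(row.get("subject_id", -1)))
                reps.append(int(row.get("repetition_id", -1)))
        order = sorted(range(len(names)), key=lambda i: names[i])
        remap = {old: new for new, old in enumerate(order)}
        return SignatureDataset(
            images=np.stack(images),
            labels=np.array([remap[l] for l in labels]),
            subjects=np.array(subjects),
            repetitions=np.array(reps),
            class_names=tuple(names[i] for i in order),
        )
    with h5py.File(path, "r") as f:
        return SignatureDataset(
            images=f["images"][:],
            labels=f["labels"][:],
            subjects=f["subjects"][:],
            repetitions=f["repetitions"][:],
            class_names=tuple(f.attrs["class_names"]),
        )
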