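"""Synthetic two-channel CTG-like records with known ground truth.

Records are sums of AM/FM tones inside the physiological 0.004-0.5 Hz band,
riding on channel baselines (140 bpm FHR, 20 a.u. UC), with controllable
cross-channel phase lag per tone, additive Gaussian noise, and optional
sensor-loss artifacts (additive spikes, NaN gaps). Every record is fully
reproducible from its seed. Labeled two-class datasets plant a directional
contrast mirroring what is seen clinically in cesarean-bound tracings —
reduced uterine-contraction tone energy and a tighter (less jittered)
FHR-UC phase relation — without claiming any particular magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CTGRecord, Label


@dataclass(frozen=True)
class Tone:
    """One shared oscillation: frequency (Hz), per-channel amplitudes, and the
    UC phase lag relative to FHR (rad). Optional slow AM envelope
    ``1 + am_depth * cos(2*pi*am_freq*t)``."""

    freq: float
    amp_fhr: float
    amp_uc: float
    phase_lag: float = 0.0
    am_freq: float | None = None
    am_depth: float = 0.0


@dataclass(frozen=True)
class ArtifactSpec:
    spike_rate_per_min: float = 0.0
    spike_magnitude: float = 0.0
    gap_count: int = 0
    gap_length_s: float = 0.0


#: default tone pair: a contraction-band tone and a slow baseline oscillation.
#: Non-zero UC phase lags reflect the delayed FHR response to contractions and
#: keep the complex trajectory genuinely bivariate (collinear channels make
#: directional envelopes degenerate).
DEFAULT_TONES = (Tone(0.25, 8.0, 4.0, phase_lag=np.pi / 3),
                 Tone(0.02, 15.0, 10.0, phase_lag=np.pi / 2))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for one record. ``seed`` is mandatory."""

    seed: int
    duration_s: float = 600.0
    fs: float = 4.0
    tones: tuple[Tone, ...] = DEFAULT_TONES
    fhr_baseline: float = 140.0
    uc_baseline: float = 20.0
    noise_sd_fhr: float = 0.0
    noise_sd_uc: float = 0.0
    artifact: ArtifactSpec = field(default_factory=ArtifactSpec)
    random_start_phase: bool = True

    def __post_init__(self) -> None:
        if self.duration_s * self.fs < 256:
            raise ValueError("duration_s * fs must be at least 256 samples")
        for tone in self.tones:
            if not 0 < tone.freq < self.fs / 2:
                raise ValueError(f"tone frequency {tone.freq} outside (0, fs/2)")


def gen_record(spec: SyntheticSpec, record_id: str = "synth",
               label: Label = Label.UNKNOWN) -> CTGRecord:
    """Generate one record; bit-identical for identical spec (same seed)."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    fhr = np.full(n, spec.fhr_baseline)
    uc = np.full(n, spec.uc_baseline)
    for tone in spec.tones:
        phi0 = rng.uniform(0, 2 * np.pi) if spec.random_start_phase else 0.0
        env = 1.0 + tone.am_depth * np.cos(2 * np.pi * tone.am_freq * t) \
            if tone.am_freq else 1.0
        w = 2 * np.pi * tone.freq * t + phi0
        fhr = fhr + tone.amp_fhr * env * np.cos(w)
        uc = uc + tone.amp_uc * env * np.cos(w + tone.phase_lag)
    if spec.noise_sd_fhr > 0:
        fhr = fhr + rng.normal(0, spec.noise_sd_fhr, n)
    if spec.noise_sd_uc > 0:
        uc = uc + rng.normal(0, spec.noise_sd_uc, n)
    rec = CTGRecord(record_id, fhr, uc, fs=spec.fs, label=label)
    a = spec.artifact
    if a.spike_rate_per_min > 0 or a.gap_count > 0:
        rec = inject_artifacts(rec, a, seed=spec.seed + 1)
    return rec


def inject_artifacts(rec: CTGRecord, art: ArtifactSpec, seed: int = 0) -> CTGRecord:
    """Seeded sensor-loss artifacts: additive FHR spikes and NaN gaps.

    Emulates contact loss — an abrupt level jump and stretches of missing
    samples (both channels). Ground-truth positions are stored in
    ``meta['injected_spikes']`` (sample indices) and ``meta['injected_gaps']``
    (``(start_s, length_s)``) for preprocessing round-trip tests.
    """
    rng = np.random.default_rng(seed)
    n = len(rec)
    gap_len = int(round(art.gap_length_s * rec.fs))
    if art.gap_count * gap_len > n:
        raise ValueError("requested gaps longer than the record")
    fhr, uc = rec.fhr.copy(), rec.uc.copy()
    n_spikes = int(round(art.spike_rate_per_min * rec.duration_s / 60.0))
    spike_idx = np.sort(rng.choice(n, size=n_spikes, replace=False)) if n_spikes else \
        np.array([], dtype=int)
    fhr[spike_idx] += art.spike_magnitude
    gaps: list[tuple[float, float]] = []
    occupied = np.zeros(n, bool)
    occupied[spike_idx] = True
    for _ in range(art.gap_count):
        for _attempt in range(100):
            s = int(rng.integers(0, n - gap_len + 1))
            if not occupied[s: s + gap_len].any():
                break
        fhr[s: s + gap_len] = np.nan
        uc[s: s + gap_len] = np.nan
        occupied[s: s + gap_len] = True
        gaps.append((s / rec.fs, gap_len / rec.fs))
    meta = {**rec.meta, "injected_spikes": spike_idx.tolist(),
            "injected_gaps": gaps}
    return replace(rec, fhr=fhr, uc=uc, meta=meta)


@dataclass(frozen=True)
class ClassEffectSpec:
    """Two-class dataset description: a base spec plus per-class deltas.

    Class order is (vaginal, cesarean). ``uc_amp_scale`` multiplies every UC
    tone amplitude; ``lag_jitter_sd`` adds per-record Gaussian jitter (rad) to
    each tone's phase lag; ``amp_jitter_rel`` applies a shared per-record
    lognormal amplitude factor per channel (record-to-record heterogeneity).
    """

    base: SyntheticSpec
    n_per_class: int
    seed: int
    uc_amp_scale: tuple[float, float] = (1.0, 1.0)
    lag_jitter_sd: tuple[float, float] = (0.0, 0.0)
    amp_jitter_rel: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_class < 10:
            raise ValueError("n_per_class must be >= 10")


def gen_dataset(effects: ClassEffectSpec,
                n_majority: int | None = None) -> list[CTGRecord]:
    """Labeled records for both classes; per-record seeds derived from the
    master seed. ``n_majority`` optionally overrides the vaginal-class count
    (for imbalanced designs); the cesarean class always has ``n_per_class``.
    """
    ss = np.random.SeedSequence(effects.seed)
    n_vag = n_majority if n_majority is not None else effects.n_per_class
    records: list[CTGRecord] = []
    counts = {Label.VAGINAL: n_vag, Label.CESAREAN: effects.n_per_class}
    for cls_idx, (label, count) in enumerate(counts.items()):
        for i in range(count):
            child = ss.spawn(1)[0]
            rec_seed = int(child.generate_state(1)[0] % (2 ** 31))
            jrng = np.random.default_rng(rec_seed)
            amp_fac = float(np.exp(jrng.normal(0, effects.amp_jitter_rel))) \
                if effects.amp_jitter_rel > 0 else 1.0
            tones = tuple(
                replace(
                    tone,
                    amp_uc=tone.amp_uc * effects.uc_amp_scale[cls_idx] * amp_fac,
                    amp_fhr=tone.amp_fhr * amp_fac,
                    phase_lag=tone.phase_lag
                    + float(jrng.normal(0, effects.lag_jitter_sd[cls_idx]))
                    if effects.lag_jitter_sd[cls_idx] > 0 else tone.phase_lag,
                )
                for tone in effects.base.tones
            )
            spec = replace(effects.base, tones=tones, seed=rec_seed + 1)
            records.append(gen_record(spec, record_id=f"{label.value}_{i:03d}",
                                      label=label))
    return records


# -- preset class contrasts ---------------------------------------------------

def strong_contrast(n_per_class: int, seed: int,
                    duration_s: float = 300.0) -> ClassEffectSpec:
    """Well-separated classes: cesarean-like records have UC tone amplitudes
    scaled by 0.4 (a large mean-energy deficit relative to the record-to-
    record spread)."""
    base = SyntheticSpec(seed=0, duration_s=duration_s,
                         noise_sd_fhr=1.0, noise_sd_uc=1.0)
    return ClassEffectSpec(base=base, n_per_class=n_per_class, seed=seed,
                           uc_amp_scale=(1.0, 0.4),
                           lag_jitter_sd=(0.6, 0.2), amp_jitter_rel=0.15)


def moderate_contrast(n_per_class: int, seed: int,
                      duration_s: float = 300.0) -> ClassEffectSpec:
    """Overlapping classes: cesarean UC amplitudes scaled by 0.7 against a
    0.35 lognormal record-to-record amplitude spread (~1 SD effect on UC mean
    energy) plus tighter cesarean phase locking; no single feature separates
    the classes, only their combination does."""
    base = SyntheticSpec(seed=0, duration_s=duration_s,
                         noise_sd_fhr=1.0, noise_sd_uc=1.0)
    return ClassEffectSpec(base=base, n_per_class=n_per_class, seed=seed,
                           uc_amp_scale=(1.0, 0.7),
                           lag_jitter_sd=(0.6, 0.2), amp_jitter_rel=0.35)


def null_contrast(n_per_class: int, seed: int,
                  duration_s: float = 300.0) -> ClassEffectSpec:
    """Zero class contrast: the labels carry no signal."""
    base = SyntheticSpec(seed=0, duration_s=duration_s,
                         noise_sd_fhr=1.0, noise_sd_uc=1.0)
    return ClassEffectSpec(base=base, n_per_class=n_per_class, seed=seed,
                           uc_amp_scale=(1.0, 1.0),
                           lag_jitter_sd=(0.5, 0.5), amp_jitter_rel=0.35)
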