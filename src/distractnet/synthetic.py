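"""Synthetic multichannel EEG-like cohorts with controlled cross-channel coupling.

Signal model
------------
Each epoch is a superposition over the four canonical bands.  Within a band
``b``, channels belonging to a *coupled group* receive a mixture

    x_ch = kappa_b * s_b + (1 - kappa_b) * e_ch,b

of one shared narrowband Gaussian process ``s_b`` (one per group per band)
and an independent narrowband process ``e_ch,b``; channels outside every
group receive only their own independent component.  All narrowband
processes are synthesized exactly in the frequency domain (complex Gaussian
amplitudes on the FFT bins inside the band), so band purity is exact and
the coupling dial ``kappa_b`` maps monotonically onto phase locking and
coherence between group members.  Broadband Gaussian noise of standard
deviation ``noise_std`` is added on top.

When ``nonlinear=True`` a pair of unidirectionally coupled Henon maps
(driver -> response, coupling constant ``nonlinear_strength``) is
superimposed on the first two channels of the first coupled group; this
generalized-synchronization component is what the synchronization-
likelihood estimator is sensitive to beyond linear mixing.

The default per-state coupling levels are synthetic conventions chosen to
qualitatively mirror the distracted-driving signatures the analysis
targets — theta and beta coupling elevated under distraction, alpha
slightly depressed — not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from distractnet.bands import BAND_ORDER, CANONICAL_BANDS
from distractnet.preprocessing import LabeledEpoch, Recording, STATES

__all__ = [
    "STATES",
    "StateCouplingSpec",
    "CohortSpec",
    "default_state_specs",
    "null_state_specs",
    "generate_epoch",
    "generate_cohort",
    "coupled_henon",
    "narrowband_noise",
]

_DEFAULT_AMPLITUDE = {"delta": 1.0, "theta": 1.0, "alpha": 1.2, "beta": 0.8}


@dataclass(frozen=True)
class StateCouplingSpec:
    """Per-state coupling structure: band coupling strengths and group layout.

    Parameters
    ----------
    state : one of ``normal``, ``cognitive``, ``visual``.
    kappa : band name -> coupling strength in [0, 1].
    coupled_groups : tuples of channel indices; each group shares one
        narrowband driver per band.  ``None`` defaults to a single group
        over the first half of the channels at generation time.
    nonlinear : superimpose a unidirectionally coupled Henon-map pair on
        the first two channels of the first group.
    nonlinear_strength : Henon coupling constant in [0, 1]; defaults to
        the maximum band kappa when unset.
    nonlinear_amplitude : RMS scale of the Henon component.
    noise_std : standard deviation of additive broadband noise (signal units).
    amplitude : band name -> oscillator RMS amplitude.
    """

    state: str
    kappa: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BAND_ORDER}
    )
    coupled_groups: tuple[tuple[int, ...], ...] | None = None
    nonlinear: bool = False
    nonlinear_strength: float | None = None
    nonlinear_amplitude: float = 0.6
    noise_std: float = 0.3
    amplitude: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDE))

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        for b, k in self.kappa.items():
            if b not in CANONICAL_BANDS:
                raise ValueError(f"unknown band {b!r} in kappa")
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"kappa[{b!r}]={k} outside [0, 1]")
        if self.noise_std < 0:
            raise ValueError(f"noise_std must be >= 0, got {self.noise_std}")
        if self.nonlinear_strength is not None and not 0.0 <= self.nonlinear_strength <= 1.0:
            raise ValueError("nonlinear_strength must lie in [0, 1]")

    def resolved_groups(self, n_channels: int) -> tuple[tuple[int, ...], ...]:
        if self.coupled_groups is None:
            return (tuple(range(n_channels // 2)),)
        for g in self.coupled_groups:
            for ch in g:
                if not 0 <= ch < n_channels:
                    raise ValueError(
                        f"coupled group channel {ch} outside [0, {n_channels})"
                    )
        return self.coupled_groups


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic cohort: subjects x states x epochs."""

    n_subjects: int = 6
    epochs_per_state: int = 10
    n_channels: int = 63
    fs: float = 512.0
    epoch_seconds: float = 10.0
    seed: int = 0
    state_specs: Mapping[str, StateCouplingSpec] = field(
        default_factory=lambda: default_state_specs()
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.epochs_per_state < 1 or self.n_channels < 1:
            raise ValueError("n_subjects, epochs_per_state and n_channels must all be >= 1")
        n = self.epoch_seconds * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"epoch_seconds * fs = {n} is not an integer sample count"
            )
        missing = set(STATES) - set(self.state_specs)
        if missing:
            raise ValueError(f"state_specs missing states: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * self.fs))


def default_state_specs(
    noise_std: float = 0.3,
    coupled_groups: tuple[tuple[int, ...], ...] | None = None,
) -> dict[str, StateCouplingSpec]:
    """Default per-state coupling levels (synthetic conventions).

    Theta coupling is strongly elevated under visual distraction and beta
    under cognitive distraction; alpha is slightly depressed under both
    distracted states; the cognitive state additionally carries the
    nonlinear (Henon) component, giving the SL estimator a signature that
    the linear estimators under-weight.
    """
    common = dict(noise_std=noise_std, coupled_groups=coupled_groups)
    return {
        "normal": StateCouplingSpec(
            "normal",
            kappa={"delta": 0.20, "theta": 0.15, "alpha": 0.35, "beta": 0.15},
            **common,
        ),
        "cognitive": StateCouplingSpec(
            "cognitive",
            kappa={"delta": 0.20, "theta": 0.25, "alpha": 0.30, "beta": 0.45},
            nonlinear=True,
            nonlinear_strength=0.8,
            **common,
        ),
        "visual": StateCouplingSpec(
            "visual",
            kappa={"delta": 0.25, "theta": 0.50, "alpha": 0.30, "beta": 0.25},
            **common,
        ),
    }


def null_state_specs(noise_std: float = 0.3) -> dict[str, StateCouplingSpec]:
    """Three states sharing identical coupling — the no-effect null cohort."""
    base = default_state_specs(noise_std=noise_std)["normal"]
    return {s: replace(base, state=s) for s in STATES}


def narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-RMS Gaussian process with spectral support exactly in [lo, hi).

    Synthesized in the frequency domain: i.i.d. complex Gaussian amplitudes
    on the rFFT bins whose frequency lies in the band, zeros elsewhere.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"no FFT bin inside band [{lo}, {hi}) Hz at n={n}, fs={fs}")
    spec = np.zeros(len(freqs), dtype=complex)
    k = int(mask.sum())
    spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def coupled_henon(
    n: int,
    coupling: float,
    rng: np.random.Generator,
    a: float = 1.4,
    b: float = 0.3,
    transient: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Unidirectionally coupled Henon maps (driver x -> response y).

    The response map replaces a fraction ``coupling`` of its own state with
    the driver's:  y_{t+1} = a - (C x_t + (1-C) y_t) y_t + b y_{t-1}.
    At ``coupling`` = 0 the two maps are independent; near 1 the response
    generalized-synchronizes onto the driver.  Trajectories start from
    random initial conditions, discard a transient, and are standardized.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError(f"coupling must lie in [0, 1], got {coupling}")
    total = n + transient
    x = np.empty(total)
    y = np.empty(total)
    # start inside the attractor basin
    x[0], x[1] = rng.uniform(-0.5, 0.5, size=2)
    y[0], y[1] = rng.uniform(-0.5, 0.5, size=2)
    for t in range(1, total - 1):
        x[t + 1] = a - x[t] ** 2 + b * x[t - 1]
        drive = coupling * x[t] + (1.0 - coupling) * y[t]
        y[t + 1] = a - drive * y[t] + b * y[t - 1]
        # numerical escape guard: re-inject near the attractor
        if not (np.isfinite(x[t + 1]) and np.isfinite(y[t + 1])):
            x[t + 1], y[t + 1] = rng.uniform(-0.5, 0.5, size=2)
    xs, ys = x[transient:], y[transient:]
    xs = (xs - xs.mean()) / xs.std()
    ys = (ys - ys.mean()) / ys.std()
    return xs, ys


def generate_epoch(
    spec: StateCouplingSpec,
    n_channels: int,
    fs: float,
    duration: float,
    seed: int,
) -> Recording:
    """Generate one multichannel epoch; a pure function of ``(spec, seed)``.

    Channels in each coupled group share one narrowband driver per band
    mixed with weight ``kappa_b``; all other channels are independent given
    the additive noise floor.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    n = duration * fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"duration * fs = {n} is not an integer sample count")
    n = int(round(n))
    groups = spec.resolved_groups(n_channels)
    grouped = {ch: gi for gi, g in enumerate(groups) for ch in g}

    rng = np.random.default_rng(seed)
    out = np.zeros((n_channels, n))
    for band_name in BAND_ORDER:
        band = CANONICAL_BANDS[band_name]
        kappa = float(spec.kappa.get(band_name, 0.0))
        amp = float(spec.amplitude.get(band_name, 1.0))
        shared = [narrowband_noise(rng, n, fs, band.lo, band.hi) for _ in groups]
        for ch in range(n_channels):
            own = narrowband_noise(rng, n, fs, band.lo, band.hi)
            if ch in grouped:
                sig = kappa * shared[grouped[ch]] + (1.0 - kappa) * own
            else:
                sig = own
            out[ch] += amp * sig

    if spec.nonlinear and groups and len(groups[0]) >= 2:
        strength = (
            spec.nonlinear_strength
            if spec.nonlinear_strength is not None
            else max(spec.kappa.values(), default=0.0)
        )
        xs, ys = coupled_henon(n, strength, rng)
        i, j = groups[0][0], groups[0][1]
        out[i] += spec.nonlinear_amplitude * xs
        out[j] += spec.nonlinear_amplitude * ys

    if spec.noise_std > 0:
        out += rng.normal(0.0, spec.noise_std, size=out.shape)
    return Recording(out, fs)


def epoch_seed(master_seed: int, subject: int, state: str, epoch_index: int) -> int:
    """Stable per-epoch seed derived from the master seed (below 2**31)."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=(int(subject), STATES.index(state), int(epoch_index)),
    )
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(spec: CohortSpec) -> list[LabeledEpoch]:
    """Generate the full labeled cohort: subjects x states x epochs_per_state."""
    epochs: list[LabeledEpoch] = []
    for subject in range(spec.n_subjects):
        for state in STATES:
            sspec = spec.state_specs[state]
            for k in range(spec.epochs_per_state):
                seed = epoch_seed(spec.seed, subject, state, k)
                rec = generate_epoch(
                    sspec, spec.n_channels, spec.fs, spec.epoch_seconds, seed
                )
                epochs.append(
                    LabeledEpoch(
                        rec.samples,
                        rec.fs,
                        state,
                        list(rec.channels),
                        subject=subject,
                        epoch_index=k,
                    )
                )
    return epochs
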