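"""Synthetic community-health datasets with the structure the method assumes.

The generator emulates the study conditions the screening pipeline was
designed for: 2299 client records with 567 numeric features split into a
profile group (132 columns, 96 of them fully observed) and an assessment
group (435 columns, all with missing values), per-feature missing rates
following the observed distribution over rate bins, and class imbalance of
427 high-risk versus 1872 normal cases (1 : 4.4).

Signal is injected through two class-conditional latent factors — one per
feature group — with linear loadings plus Gaussian noise, so each group
carries its own predictive information (the structural premise for the
dual architecture). Missingness is MCAR by default, i.e. independent of the
label and of any value; an optional MAR mode ties the missing probability
of each cell to a fully observed profile covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    DataError,
    FeatureTable,
    GroupSpec,
    LabelVector,
    MMSE_CUTOFF,
    MMSE_MAX,
)

#: (low %, high %, number of features) per missing-rate bin; the zero bin is
#: the fully observed features.
DEFAULT_MISSING_BINS: tuple[tuple[int, int, int], ...] = (
    (0, 0, 96),
    (1, 9, 49),
    (10, 19, 22),
    (20, 29, 6),
    (30, 39, 97),
    (40, 49, 5),
    (50, 59, 152),
    (60, 69, 140),
)

#: Lowest missing rate among assessment features; assessment columns landing
#: in the 1-9% bin draw their rate from [4.9%, 9%] rather than [1%, 9%].
ASSESSMENT_MIN_RATE = 0.049

DEFAULT_M = 2299
DEFAULT_N_P = 132
DEFAULT_N_Q = 435
DEFAULT_N_COMPLETE = 96
DEFAULT_MINORITY = 427


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults reproduce the emulated study structure.

    ``signal_profile`` / ``signal_assessment`` scale the class separation of
    each group's latent factor (0 = that group carries no signal);
    ``noise_sd`` is the per-feature Gaussian noise standard deviation;
    ``binary_fraction`` of assessment columns is thresholded at the median
    to mimic yes/no questionnaire items. Profile columns are given
    heterogeneous units: each is rescaled by a factor drawn log-uniformly
    over ``profile_scale_decades`` decades and shifted to a positive
    baseline, emulating raw bio-measurements (blood pressure, temperature,
    pulse, ratios) that are fed to the models without preprocessing. This
    per-column rescaling multiplies signal and noise together, so the
    per-feature signal-to-noise ratio is untouched.
    """

    m: int = DEFAULT_M
    n_p: int = DEFAULT_N_P
    n_q: int = DEFAULT_N_Q
    n_complete: int = DEFAULT_N_COMPLETE
    missing_bins: tuple[tuple[int, int, int], ...] = DEFAULT_MISSING_BINS
    minority_count: int = DEFAULT_MINORITY
    latent_dim: int = 8
    signal_profile: float = 0.6
    signal_assessment: float = 0.6
    noise_sd: float = 1.0
    binary_fraction: float = 0.5
    profile_scale_decades: float = 1.5
    mar: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_p + self.n_q
        total = sum(count for _, _, count in self.missing_bins)
        if total != n:
            raise DataError(f"missing-bin counts sum to {total}, expected n={n}")
        zero = sum(c for lo, hi, c in self.missing_bins if hi == 0)
        if zero != self.n_complete:
            raise DataError("zero-rate bin count must equal n_complete")
        if self.n_complete > self.n_p:
            raise DataError("all complete features must fit in the profile group")
        if not 0 < self.minority_count < self.m:
            raise DataError("minority_count must lie strictly between 0 and m")
        if self.m < 2 or self.latent_dim < 1:
            raise DataError("m must be >= 2 and latent_dim >= 1")
        if self.signal_profile < 0 or self.signal_assessment < 0 or self.noise_sd <= 0:
            raise DataError("signals must be >= 0 and noise_sd > 0")
        if not 0 <= self.binary_fraction <= 1:
            raise DataError("binary_fraction must lie in [0, 1]")
        if self.profile_scale_decades < 0:
            raise DataError("profile_scale_decades must be >= 0")

    @property
    def n(self) -> int:
        return self.n_p + self.n_q

    @staticmethod
    def scaled(m: int, seed: int = 0, **overrides) -> "SynthConfig":
        """Default feature structure with the record count scaled to m.

        The minority count is scaled proportionally, preserving the
        1 : 4.4 class ratio.
        """
        minority = max(1, round(m * DEFAULT_MINORITY / DEFAULT_M))
        return SynthConfig(m=m, minority_count=minority, seed=seed, **overrides)


def small_config(
    m: int = 300,
    n_p: int = 12,
    n_q: int = 24,
    n_complete: int = 9,
    seed: int = 0,
    **overrides,
) -> SynthConfig:
    """A reduced-width config for fast experiments and tests.

    The incomplete columns are spread over the seven nonzero default bins
    in proportion to their default counts (largest-remainder rounding), so
    the missingness profile keeps the same shape at any width.
    """
    n_incomplete = n_p + n_q - n_complete
    nonzero = [(lo, hi, c) for lo, hi, c in DEFAULT_MISSING_BINS if hi > 0]
    weight = sum(c for _, _, c in nonzero)
    exact = [n_incomplete * c / weight for _, _, c in nonzero]
    counts = [int(np.floor(e)) for e in exact]
    remainders = np.array(exact) - np.array(counts)
    for idx in np.argsort(-remainders)[: n_incomplete - sum(counts)]:
        counts[idx] += 1
    bins = [(0, 0, n_complete)] + [
        (lo, hi, c) for (lo, hi, _), c in zip(nonzero, counts) if c > 0
    ]
    minority = max(1, round(m * DEFAULT_MINORITY / DEFAULT_M))
    return SynthConfig(
        m=m,
        n_p=n_p,
        n_q=n_q,
        n_complete=n_complete,
        missing_bins=tuple(bins),
        minority_count=overrides.pop("minority_count", minority),
        seed=seed,
        **overrides,
    )


def _group_signal(
    rng: np.random.Generator,
    y_signed: np.ndarray,
    n_cols: int,
    latent_dim: int,
    signal: float,
    noise_sd: float,
) -> tuple[np.ndarray, dict]:
    direction = rng.normal(size=latent_dim)
    direction /= np.linalg.norm(direction)
    latents = signal * np.outer(y_signed, direction) + rng.normal(
        size=(len(y_signed), latent_dim)
    )
    loadings = rng.normal(size=(latent_dim, n_cols)) / np.sqrt(latent_dim)
    X = latents @ loadings + noise_sd * rng.normal(size=(len(y_signed), n_cols))
    return X, {"direction": direction, "latents": latents, "loadings": loadings}


def _target_rates(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-column target missing rate, in column order (profile then assessment).

    Complete columns (rate 0) lead the profile group. The remaining profile
    columns take the lowest nonzero bins; all later slots belong to the
    assessment group, whose lowest rates are floored at 4.9%.
    """
    n = cfg.n
    rates = np.zeros(n)
    slots: list[tuple[float, float]] = []
    for lo, hi, count in sorted(cfg.missing_bins, key=lambda b: b[0]):
        if hi == 0:
            continue
        slots.extend([(lo / 100.0, hi / 100.0)] * count)
    for offset, (lo, hi) in enumerate(slots):
        col = cfg.n_complete + offset
        if col >= cfg.n_p:  # assessment column
            lo = max(lo, ASSESSMENT_MIN_RATE)
        rates[col] = rng.uniform(lo, min(hi, 0.95))
    return rates


def generate(
    cfg: SynthConfig,
) -> tuple[FeatureTable, GroupSpec, LabelVector, dict]:
    """Draw one dataset; returns (table, groups, labels, ground truth).

    The truth record stores the latent factors, loadings, per-column target
    missing rates and the binarized-column ids, for downstream checks of
    generator fidelity.
    """
    seq = np.random.SeedSequence([cfg.seed, 2718281]).spawn(4)
    rng_labels, rng_signal, rng_mask, rng_binary = (
        np.random.default_rng(s) for s in seq
    )

    y = np.zeros(cfg.m, dtype=int)
    y[rng_labels.permutation(cfg.m)[: cfg.minority_count]] = 1
    y_signed = 2.0 * y - 1.0

    Xp, truth_p = _group_signal(
        rng_signal, y_signed, cfg.n_p, cfg.latent_dim, cfg.signal_profile, cfg.noise_sd
    )
    Xq, truth_q = _group_signal(
        rng_signal, y_signed, cfg.n_q, cfg.latent_dim, cfg.signal_assessment, cfg.noise_sd
    )

    profile_cols = tuple(f"p{j:03d}" for j in range(cfg.n_p))
    assessment_cols = tuple(f"a{j:03d}" for j in range(cfg.n_q))

    # heterogeneous measurement units for the profile group (no preprocessing
    # is applied downstream, mirroring how the raw measurements are consumed)
    if cfg.profile_scale_decades > 0:
        scales = 10.0 ** rng_signal.uniform(0.0, cfg.profile_scale_decades, cfg.n_p)
        offsets = scales * rng_signal.uniform(1.0, 3.0, cfg.n_p)
        Xp = offsets + scales * Xp
        truth_p["scales"], truth_p["offsets"] = scales, offsets

    n_binary = int(round(cfg.binary_fraction * cfg.n_q))
    binary_idx = np.sort(rng_binary.permutation(cfg.n_q)[:n_binary])
    for j in binary_idx:
        Xq[:, j] = (Xq[:, j] > np.median(Xq[:, j])).astype(float)

    values = np.concatenate([Xp, Xq], axis=1)
    rates = _target_rates(cfg, rng_mask)

    mask = np.ones((cfg.m, cfg.n), dtype=bool)
    if cfg.mar:
        # missing probability ramps with the first complete covariate's rank
        ranks = np.argsort(np.argsort(values[:, 0]))
        ramp = 2.0 * ranks / max(cfg.m - 1, 1)
    for col in range(cfg.n):
        r = rates[col]
        if r == 0:
            continue
        if cfg.mar:
            miss = rng_mask.random(cfg.m) < np.clip(r * ramp, 0.0, 0.98)
        else:
            miss = rng_mask.random(cfg.m) < r
        if not miss.any():  # incomplete columns must have >= 1 missing cell
            miss[rng_mask.integers(cfg.m)] = True
        if miss.all():
            miss[rng_mask.integers(cfg.m)] = False
        mask[:, col] = ~miss

    table = FeatureTable(
        values,
        mask,
        profile_cols + assessment_cols,
        tuple(f"r{i:04d}" for i in range(cfg.m)),
    )
    spec = GroupSpec.from_table(table, profile_cols, assessment_cols)
    truth = {
        "config": cfg,
        "profile": truth_p,
        "assessment": truth_q,
        "target_rates": rates,
        "binary_assessment_columns": tuple(assessment_cols[j] for j in binary_idx),
    }
    return table, spec, LabelVector(y), truth


def mmse_scores_from_labels(labels: LabelVector, seed: int = 0) -> np.ndarray:
    """Draw MMSE scores consistent with the labels, so derivation inverts.

    Normal cases score uniformly in [24, 30], high-risk cases in [0, 23].
    """
    rng = np.random.default_rng(seed)
    y = labels.labels
    scores = np.where(
        y == 1,
        rng.integers(0, MMSE_CUTOFF, size=len(y)),
        rng.integers(MMSE_CUTOFF, MMSE_MAX + 1, size=len(y)),
    )
    return scores.astype(int)
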