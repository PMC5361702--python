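"""Seeded generator of multi-batch LC-MS peak tables with known ground truth.

The generator emulates the structure of a typical untargeted plasma
metabolomics run: log-normal feature abundances, a case/control design
split across batches, pooled-QC injections at regular positions in the run
sequence, multiplicative signal drift along injection order, per-batch
additive offsets on the log scale, and intensity-dependent (MNAR)
missingness — the dropout mechanism the detection-rate filters target.

Every stochastic choice flows from one integer seed, so the same call is
bit-reproducible; the returned :class:`SimTruth` records which features are
differential, their log2 effect sizes, the batch offsets and the drift
parameters, enabling parameter-recovery experiments against the pipeline.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import PeakTable, SampleMeta

__all__ = ["SimTruth", "simulate_peak_table"]


@dataclasses.dataclass
class SimTruth:
    """Ground truth of a simulated peak table."""

    diff_features: np.ndarray          # feature ids with a group effect
    effects_log2: np.ndarray           # signed log2 effect per diff feature
    batch_offsets: np.ndarray          # (n_features, n_batches) log2 offsets
    drift: str                         # drift shape name
    drift_amplitude: np.ndarray        # (n_features,) signed log2 amplitude
    drift_phase: np.ndarray            # (n_batches,) phase for smooth drift
    mnar_strength: float
    noise_sd: float
    seed: int


def simulate_peak_table(
    n_features: int = 1000,
    n_case: int = 50,
    n_control: int = 50,
    n_batches: int = 2,
    qc_every: int = 5,
    drift: str = "smooth",
    drift_magnitude: float = 0.3,
    batch_sd: float = 0.3,
    n_diff: int = 50,
    effect_log2: float = 1.0,
    mnar_strength: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    case_label: str = "case",
    control_label: str = "control",
) -> tuple[PeakTable, SampleMeta, SimTruth]:
    """Simulate a peak table, its sample list and the generating truth.

    Parameters
    ----------
    n_features, n_case, n_control, n_batches
        Dimensions of the experiment; biological samples are split evenly
        across batches with balanced groups.
    qc_every
        A pooled-QC injection occupies every ``qc_every``-th position of
        each batch's run sequence (must be >= 2).
    drift
        ``"none"``, ``"linear"`` (monotone across a batch) or ``"smooth"``
        (one sinusoidal period per batch).  Applied multiplicatively, i.e.
        additively on the log2 scale, with a per-feature random amplitude
        in ``drift_magnitude * U(0.5, 1.5)`` and random sign.
    batch_sd
        SD of the per-feature, per-batch additive log2 offset.
    n_diff, effect_log2
        Number of differential features and the scale of their effects;
        each effect is ``effect_log2 * U(0.5, 1.5)`` with random sign,
        added to case samples.
    mnar_strength
        Slope of the logistic missingness model in log2 intensity; 0
        disables missingness entirely.  Cells far below the 5th percentile
        of the clean log2 intensities are most likely to drop out.
    noise_sd
        Per-cell measurement noise SD on the log2 scale (QCs included:
        pooled-mean profile plus the same measurement noise).

    Returns
    -------
    (PeakTable, SampleMeta, SimTruth)
    """
    if min(n_features, n_case, n_control, n_batches) < 1:
        raise ValueError("counts must be positive")
    if qc_every < 2:
        raise ValueError("qc_every must be >= 2")
    if not 0 <= n_diff <= n_features:
        raise ValueError("n_diff must be in [0, n_features]")
    if drift not in ("none", "linear", "smooth"):
        raise ValueError(f"unknown drift shape {drift!r}")

    rng = np.random.default_rng(seed)

    # per-feature baseline abundance (log2 scale, lognormal intensities)
    mu = rng.normal(17.0, 2.0, size=n_features)

    diff_idx = rng.choice(n_features, size=n_diff, replace=False) if n_diff else np.array([], dtype=int)
    effects = np.zeros(n_features)
    if n_diff:
        magnitude = effect_log2 * rng.uniform(0.5, 1.5, size=n_diff)
        sign = rng.choice([-1.0, 1.0], size=n_diff)
        effects[diff_idx] = magnitude * sign

    batch_offsets = rng.normal(0.0, batch_sd, size=(n_features, n_batches)) if batch_sd > 0 else np.zeros((n_features, n_batches))

    amp = drift_magnitude * rng.uniform(0.5, 1.5, size=n_features) * rng.choice([-1.0, 1.0], size=n_features)
    phase = rng.uniform(0, 2 * np.pi, size=n_batches)

    # --- design: assign biological samples to batches, build run sequences
    n_bio = n_case + n_control
    groups = np.array([case_label] * n_case + [control_label] * n_control, dtype=object)
    perm = rng.permutation(n_bio)
    groups = groups[perm]
    bio_names = np.array(
        [f"S{i+1:03d}" for i in range(n_bio)], dtype=object
    )
    batch_of_bio = np.arange(n_bio) % n_batches  # balanced interleave

    sample_ids: list[str] = []
    sample_batch: list[str] = []
    sample_class: list[str | None] = []
    sample_order: list[int] = []
    order = 0
    qc_counter = 0
    pooled_shift = effects * (n_case / n_bio)  # QC pool = mean of all biological profiles
    qc_rows: list[tuple[int, int]] = []  # (column, batch) for later intensity fill

    columns: list[tuple[str, int, float]] = []  # (kind, batch, effect multiplier)
    for b in range(n_batches):
        members = [i for i in range(n_bio) if batch_of_bio[i] == b]
        rng.shuffle(members)
        pos_in_batch = 0
        queue = list(members)
        while queue:
            pos_in_batch += 1
            order += 1
            if pos_in_batch % qc_every == 1:
                qc_counter += 1
                sample_ids.append(f"QC{qc_counter:03d}")
                sample_batch.append(str(b + 1))
                sample_class.append(None)
                sample_order.append(order)
                columns.append(("qc", b, np.nan))
            else:
                i = queue.pop(0)
                sample_ids.append(str(bio_names[i]))
                sample_batch.append(str(b + 1))
                sample_class.append(str(groups[i]))
                sample_order.append(order)
                columns.append(("bio", b, 1.0 if groups[i] == case_label else 0.0))

    n_samples = len(sample_ids)
    log2x = np.empty((n_features, n_samples))

    # per-batch position for drift evaluation
    batch_positions: dict[int, list[int]] = {b: [] for b in range(n_batches)}
    for j, (_, b, _) in enumerate(columns):
        batch_positions[b].append(j)

    for b in range(n_batches):
        cols = batch_positions[b]
        L = max(len(cols) - 1, 1)
        for rank, j in enumerate(cols):
            frac = rank / L
            if drift == "none":
                d = np.zeros(n_features)
            elif drift == "linear":
                d = amp * (2.0 * frac - 1.0)
            else:  # smooth
                d = amp * np.sin(2 * np.pi * frac + phase[b])
            kind, _, case_mult = columns[j]
            if kind == "qc":
                base = mu + pooled_shift
            else:
                base = mu + effects * case_mult
            log2x[:, j] = base + batch_offsets[:, b] + d + rng.normal(0.0, noise_sd, size=n_features)

    values = np.power(2.0, log2x)

    # --- MNAR missingness: dropout probability rises as intensity falls
    if mnar_strength > 0:
        center = np.quantile(log2x, 0.05)
        p_miss = 1.0 / (1.0 + np.exp(mnar_strength * (log2x - center)))
        mask = rng.random(size=log2x.shape) < p_miss
        # never lose a feature entirely
        for i in np.where(mask.all(axis=1))[0]:
            keep = rng.integers(0, n_samples)
            mask[i, keep] = False
    else:
        mask = np.zeros(log2x.shape, dtype=bool)

    feature_ids = np.array([f"F{i+1:05d}" for i in range(n_features)], dtype=object)
    mz = np.round(rng.uniform(80.0, 1200.0, size=n_features), 4)
    rt = np.round(rng.uniform(0.5, 18.0, size=n_features), 2)

    pt = PeakTable(feature_ids, np.array(sample_ids, dtype=object), values, mask, mz=mz, rt=rt)
    meta = SampleMeta.from_columns(sample_ids, sample_batch, sample_class, sample_order)
    truth = SimTruth(
        diff_features=feature_ids[diff_idx],
        effects_log2=effects[diff_idx],
        batch_offsets=batch_offsets,
        drift=drift,
        drift_amplitude=amp,
        drift_phase=phase,
        mnar_strength=mnar_strength,
        noise_sd=noise_sd,
        seed=seed,
    )
    return pt, meta, truth
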