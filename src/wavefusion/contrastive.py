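"""Subject-aware contrastive loss, batch composition, and augmentations.

The subject-aware contrastive (SAC) loss treats as positives only the
views that share BOTH the condition label and the subject with the anchor,
and as negatives only opposite-class views — split into intra-subject
negatives (same subject, other class, ``N_a``) and inter-subject negatives
(other subject, other class, ``N_r``).  Same-class views from *other*
subjects belong to neither set and do not enter the loss:

    L = - sum_i log[ (1/|Q(i)|) sum_{q in Q(i)} exp(z_i . z_q / tau)
                     / sum_{s in S(i)} exp(z_i . z_s / tau) ],

with ``S(i) = N_r(i) u N_a(i)``.  Note the denominator runs over the
negatives only and the mean over positives sits inside the log; the
conventional supervised-contrastive (SupCon) baseline — positives share
the class regardless of subject, denominator over all non-anchor views,
log inside the positive mean — is provided for comparison.  Anchors with
no positive or no negative are skipped with a warning.

Batches are composed per (subject, class) key by drawing a prescribed
fraction of positives, intra-subject negatives and inter-subject
negatives, which is how the batch-construction schemes of the original
study ("50/0/50" etc., read as Q / N_r / N_a percentages) are realized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import TensorDataset

logger = logging.getLogger(__name__)

#: Batch-composition schemes studied in the original work, keyed by their
#: "Q/N_r/N_a (%)" labels, plus the SupCon baseline.
SCHEME_PRESETS: dict[str, tuple[float, float, float] | None] = {
    "supcon": None,
    "12.5/37.5/50": (0.125, 0.375, 0.50),
    "25/25/50": (0.25, 0.25, 0.50),
    "37.5/12.5/50": (0.375, 0.125, 0.50),
    "45/5/50": (0.45, 0.05, 0.50),
    "5/45/50": (0.05, 0.45, 0.50),
    "50/0/50": (0.50, 0.0, 0.50),
}


# ---------------------------------------------------------------------- #
# augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """Relative amplitudes of the three view augmentations."""

    pink_noise_scale: float = 0.1
    gaussian_noise_scale: float = 0.1
    input_dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.input_dropout_rate < 1:
            raise ValueError("input_dropout_rate must be in [0, 1)")
        if min(self.pink_noise_scale, self.gaussian_noise_scale) < 0:
            raise ValueError("noise scales must be >= 0")


def pink_noise_tensor(shape: tuple[int, ...], rng: np.random.Generator,
                      freq_axis: int = -2) -> np.ndarray:
    """Gaussian noise whose expected power falls as 1/f along the
    frequency axis (bin index 1..F), normalized to unit mean power."""
    n_freq = shape[freq_axis]
    f = np.arange(1, n_freq + 1, dtype=float)
    w = 1.0 / np.sqrt(f)
    w /= np.sqrt(np.mean(w ** 2))
    bshape = [1] * len(shape)
    bshape[freq_axis] = n_freq
    return rng.standard_normal(shape) * w.reshape(bshape)


def augment(x: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """One augmented view: dropout_mask * (x + pink + gaussian).

    With all scales zero and dropout zero this is the identity.
    Operates on spectrogram arrays of shape (..., freq, time).
    """
    x = np.asarray(x, dtype=float)
    out = x
    if cfg.pink_noise_scale > 0:
        out = out + cfg.pink_noise_scale * pink_noise_tensor(x.shape, rng)
    if cfg.gaussian_noise_scale > 0:
        out = out + cfg.gaussian_noise_scale * rng.standard_normal(x.shape)
    if cfg.input_dropout_rate > 0:
        out = out * (rng.random(x.shape) >= cfg.input_dropout_rate)
    return out if out is not x else x.copy()


# ---------------------------------------------------------------------- #
# view batches


@dataclass
class ViewBatch:
    """2N augmented views with duplicated labels and source provenance."""

    views: np.ndarray        # (2N, leads, freq, time)
    y1: np.ndarray           # (2N,)
    y2: np.ndarray           # (2N,)
    provenance: np.ndarray   # (2N,) source-sample index per view

    def __post_init__(self) -> None:
        n = len(self.views)
        if n % 2 or n < 4:
            raise ValueError("a view batch holds 2N views, N >= 2")
        for arr in (self.y1, self.y2, self.provenance):
            if len(arr) != n:
                raise ValueError("label arrays must match the view count")
        if not (np.array_equal(self.y1[0::2], self.y1[1::2])
                and np.array_equal(self.y2[0::2], self.y2[1::2])):
            raise ValueError("paired views must share their labels")

    def __len__(self) -> int:
        return len(self.views)


def build_view_batch(dataset: TensorDataset, indices: np.ndarray,
                     cfg: AugmentConfig, rng: np.random.Generator
                     ) -> ViewBatch:
    """Two augmented views per selected sample, labels duplicated."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("cannot build a view batch from an empty batch")
    views = np.empty((2 * len(indices),) + dataset.X.shape[1:])
    for k, idx in enumerate(indices):
        views[2 * k] = augment(dataset.X[idx], cfg, rng)
        views[2 * k + 1] = augment(dataset.X[idx], cfg, rng)
    return ViewBatch(
        views=views,
        y1=np.repeat(dataset.y1[indices], 2),
        y2=np.repeat(dataset.y2[indices], 2),
        provenance=np.repeat(indices, 2),
    )


# ---------------------------------------------------------------------- #
# contrast sets and losses


def contrast_sets(i: int, y1: np.ndarray, y2: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positive and negative index sets for anchor ``i``.

    Returns ``(Q, N_r, N_a)``: positives share class and subject;
    inter-subject negatives differ in both; intra-subject negatives share
    the subject but differ in class.  The anchor belongs to none of them,
    and neither do same-class views from other subjects.
    """
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    other = np.arange(len(y1)) != i
    same_c = y1 == y1[i]
    same_s = y2 == y2[i]
    q = np.flatnonzero(other & same_c & same_s)
    n_r = np.flatnonzero(other & ~same_c & ~same_s)
    n_a = np.flatnonzero(other & ~same_c & same_s)
    return q, n_r, n_a


def _masked_logsumexp(sim: np.ndarray, mask: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise logsumexp over masked entries and the softmax weights."""
    neg = np.where(mask, sim, -np.inf)
    mx = neg.max(axis=1, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    e = np.exp(neg - mx)
    s = e.sum(axis=1, keepdims=True)
    lse = np.log(np.maximum(s, 1e-300)).ravel() + mx.ravel()
    soft = e / np.maximum(s, 1e-300)
    return lse, soft


def sac_loss(Z: np.ndarray, y1: np.ndarray, y2: np.ndarray,
             tau_sac: float = 0.25, return_grad: bool = False):
    """Subject-aware contrastive loss (and optionally dL/dZ).

    Summed over all anchors with at least one positive and one negative;
    degenerate anchors are skipped with a warning.  Raises if every anchor
    is degenerate.
    """
    if tau_sac <= 0:
        raise ValueError("tau_sac must be positive")
    Z = np.asarray(Z, dtype=float)
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    n = len(Z)
    sim = (Z @ Z.T) / tau_sac
    eye = np.eye(n, dtype=bool)
    q_mask = (y1[:, None] == y1[None, :]) & (y2[:, None] == y2[None, :]) & ~eye
    s_mask = (y1[:, None] != y1[None, :]) & ~eye
    valid = q_mask.any(axis=1) & s_mask.any(axis=1)
    n_skipped = int(n - valid.sum())
    if n_skipped == n:
        raise ValueError("degenerate batch: every anchor lacks a positive "
                         "or a negative")
    if n_skipped:
        logger.warning("sac_loss: skipped %d/%d degenerate anchors",
                       n_skipped, n)
    lse_q, soft_q = _masked_logsumexp(sim, q_mask)
    lse_s, soft_s = _masked_logsumexp(sim, s_mask)
    q_sizes = q_mask.sum(axis=1)
    per_anchor = -lse_q + np.log(np.maximum(q_sizes, 1)) + lse_s
    loss = float(per_anchor[valid].sum())
    if not return_grad:
        return loss
    coef = np.where(valid[:, None], soft_s * s_mask - soft_q * q_mask, 0.0)
    grad = (coef @ Z + coef.T @ Z) / tau_sac
    return loss, grad


def supcon_loss(Z: np.ndarray, y1: np.ndarray, tau_sac: float = 0.25,
                return_grad: bool = False):
    """Standard supervised-contrastive loss (class-only positives,
    all-non-anchor denominator, log inside the positive mean), summed over
    anchors with at least one same-class companion."""
    if tau_sac <= 0:
        raise ValueError("tau_sac must be positive")
    Z = np.asarray(Z, dtype=float)
    y1 = np.asarray(y1)
    n = len(Z)
    sim = (Z @ Z.T) / tau_sac
    eye = np.eye(n, dtype=bool)
    p_mask = (y1[:, None] == y1[None, :]) & ~eye
    a_mask = ~eye
    valid = p_mask.any(axis=1)
    if not valid.any():
        raise ValueError("degenerate batch: no anchor has a positive")
    if not valid.all():
        logger.warning("supcon_loss: skipped %d/%d anchors without positives",
                       int(n - valid.sum()), n)
    lse_a, soft_a = _masked_logsumexp(sim, a_mask)
    p_sizes = np.maximum(p_mask.sum(axis=1), 1)
    mean_pos_sim = (sim * p_mask).sum(axis=1) / p_sizes
    per_anchor = -mean_pos_sim + lse_a
    loss = float(per_anchor[valid].sum())
    if not return_grad:
        return loss
    coef = np.where(valid[:, None],
                    soft_a * a_mask - p_mask / p_sizes[:, None], 0.0)
    grad = (coef @ Z + coef.T @ Z) / tau_sac
    return loss, grad


# ---------------------------------------------------------------------- #
# batch composition


@dataclass(frozen=True)
class BatchCompositionSpec:
    """Fractions of positives / inter- / intra-subject negatives per batch.

    ``strict=True`` rejects fractions that do not yield integer counts at
    ``batch_size``; otherwise counts are apportioned by largest remainder
    so they always sum to ``batch_size``.
    """

    frac_positive: float
    frac_inter_negative: float
    frac_intra_negative: float
    batch_size: int
    strict: bool = False

    def __post_init__(self) -> None:
        fracs = (self.frac_positive, self.frac_inter_negative,
                 self.frac_intra_negative)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.strict:
            for f in fracs:
                raw = f * self.batch_size
                if abs(raw - round(raw)) > 1e-9:
                    raise ValueError(
                        f"fraction {f} gives non-integer count "
                        f"{raw} at batch size {self.batch_size}"
                    )

    @staticmethod
    def from_preset(name: str, batch_size: int = 500
                    ) -> "BatchCompositionSpec":
        if name not in SCHEME_PRESETS or SCHEME_PRESETS[name] is None:
            raise KeyError(f"unknown composition preset {name!r}")
        q, nr, na = SCHEME_PRESETS[name]
        return BatchCompositionSpec(q, nr, na, batch_size)

    def role_counts(self) -> dict[str, int]:
        """Integer counts per role (largest-remainder apportionment)."""
        fracs = {"positive": self.frac_positive,
                 "inter_negative": self.frac_inter_negative,
                 "intra_negative": self.frac_intra_negative}
        raw = {k: f * self.batch_size for k, f in fracs.items()}
        counts = {k: int(np.floor(v + 1e-9)) for k, v in raw.items()}
        short = self.batch_size - sum(counts.values())
        by_rem = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
        for k in by_rem[:short]:
            counts[k] += 1
        return counts


class DatasetIndex:
    """Sample indices grouped by (subject, class) for batch composition."""

    def __init__(self, dataset: TensorDataset) -> None:
        self.by_key: dict[tuple[int, int], np.ndarray] = {}
        for subj in np.unique(dataset.y2):
            for cls in (0, 1):
                idx = np.flatnonzero((dataset.y2 == subj)
                                     & (dataset.y1 == cls))
                if idx.size:
                    self.by_key[(int(subj), int(cls))] = idx
        self.subjects = sorted({k[0] for k in self.by_key})

    def keys(self) -> list[tuple[int, int]]:
        return sorted(self.by_key)

    def pool(self, subject: int, cls: int) -> np.ndarray:
        return self.by_key.get((subject, cls), np.empty(0, dtype=int))

    def inter_pool(self, subject: int, cls: int) -> np.ndarray:
        parts = [v for (s, c), v in self.by_key.items()
                 if s != subject and c == cls]
        return (np.concatenate(parts) if parts
                else np.empty(0, dtype=int))


def compose_batch(index: DatasetIndex, key: tuple[int, int],
                  spec: BatchCompositionSpec, rng: np.random.Generator
                  ) -> np.ndarray:
    """Sample indices for one batch keyed to ``key = (subject, class)``.

    Draws, without replacement within each role, the prescribed number of
    positives (key's subject and class), intra-subject negatives (same
    subject, other class) and inter-subject negatives (other subjects,
    other class).
    """
    subject, cls = key
    counts = spec.role_counts()
    pools = {
        "positive": index.pool(subject, cls),
        "intra_negative": index.pool(subject, 1 - cls),
        "inter_negative": index.inter_pool(subject, 1 - cls),
    }
    chosen = []
    for role, need in counts.items():
        pool = pools[role]
        if need > pool.size:
            raise ValueError(
                f"batch for key {key}: need {need} {role} samples, "
                f"only {pool.size} available"
            )
        if need:
            chosen.append(rng.choice(pool, size=need, replace=False))
    return np.concatenate(chosen)
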