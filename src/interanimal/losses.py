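"""Training objectives as standalone, desk-scale computations.

Supervised, reconstruction and contrastive losses are implemented as pure
functions of batches (plus explicit memory-bank / queue state for the
methods that keep one), exactly as the formulas define them, so each has
a closed-form value on constructed inputs. Training loops, optimisers and
augmentation stacks are documented reference metadata only (see
docs/methods.md) — these functions evaluate the objectives, they do not
optimise them.

Reference configurations (temperatures, negative-sample counts, momentum
coefficients) follow the published training recipes; desk-scale tests
shrink bank and queue sizes through the explicit size parameters.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "cross_entropy_loss",
    "sparse_autoencoder_loss",
    "depth_mse_loss",
    "MemoryBank",
    "instance_recognition_loss",
    "moco_loss",
    "momentum_update",
    "EmbeddingQueue",
    "simclr_loss",
    "simsiam_loss",
    "barlow_twins_loss",
    "vicreg_loss",
]


def _as2d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D (batch x dim)")
    return arr


def _unit_rows(z: np.ndarray, name: str) -> np.ndarray:
    norms = np.linalg.norm(z, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError(f"{name} contains zero vectors")
    if not np.allclose(norms, 1.0, atol=1e-6):
        logger.warning("%s not unit-normalised; normalising", name)
        z = z / norms
    return z


# -- supervised / reconstruction --------------------------------------------

def cross_entropy_loss(logits, labels) -> float:
    """Mean softmax cross-entropy, -1/N sum log softmax(X_i)[c_i]."""
    x = _as2d(logits, "logits")
    c = np.asarray(labels, dtype=int)
    if c.shape != (x.shape[0],):
        raise ValueError("labels must be a length-batch integer vector")
    if np.any(c < 0) or np.any(c >= x.shape[1]):
        raise ValueError("label index out of range")
    log_probs = x[np.arange(len(c)), c] - logsumexp(x, axis=1)
    return float(-log_probs.mean())


def sparse_autoencoder_loss(reconstruction, image, embedding,
                            lam: float = 0.0005) -> float:
    """Reconstruction + sparsity penalty on the image embedding.

    Per image with side ``S`` (64 in the reference configuration) and
    embedding dimension ``d`` (128): ``||f(x) - x||^2 / (2 S^2)
    + lam * ||v||_1 / d``, averaged over the batch.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    rec = np.asarray(reconstruction, dtype=float)
    img = np.asarray(image, dtype=float)
    if rec.shape != img.shape:
        raise ValueError("reconstruction and image shapes differ")
    if rec.ndim < 3:
        rec, img = rec[None], img[None]
    v = np.asarray(embedding, dtype=float)
    if v.ndim == 1:
        v = v[None]
    if v.shape[0] != rec.shape[0]:
        raise ValueError("embedding batch size mismatch")
    side = rec.shape[-1]
    n = rec.shape[0]
    recon = ((rec - img).reshape(n, -1) ** 2).sum(axis=1) / (2.0 * side**2)
    sparsity = lam * np.abs(v).sum(axis=1) / v.shape[1]
    return float((recon + sparsity).mean())


def depth_mse_loss(prediction, depth_map) -> float:
    """Mean-squared depth loss with per-map target normalisation.

    Each target depth map is normalised to zero mean and unit standard
    deviation across pixels before the squared error (scaled as in the
    reconstruction loss) is taken.
    """
    pred = np.asarray(prediction, dtype=float)
    depth = np.asarray(depth_map, dtype=float)
    if pred.shape != depth.shape:
        raise ValueError("prediction and depth shapes differ")
    if pred.ndim < 3:
        pred, depth = pred[None], depth[None]
    n = pred.shape[0]
    flat = depth.reshape(n, -1)
    sd = flat.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant depth map cannot be normalised")
    norm = (flat - flat.mean(axis=1, keepdims=True)) / sd
    side = pred.shape[-1]
    err = ((pred.reshape(n, -1) - norm) ** 2).sum(axis=1) / (2.0 * side**2)
    return float(err.mean())


# -- memory-bank methods -----------------------------------------------------

class MemoryBank:
    """Unit-normalised embedding store with momentum updates.

    ``update`` applies ``v <- momentum * v + (1 - momentum) * z`` followed
    by re-projection onto the unit sphere (momentum 0.5 in the reference
    configuration).
    """

    def __init__(self, vectors: np.ndarray):
        self.vectors = _unit_rows(_as2d(vectors, "bank"), "bank")

    def __len__(self) -> int:
        return len(self.vectors)

    def update(self, indices, z, momentum: float = 0.5) -> None:
        idx = np.asarray(indices, dtype=int)
        z = _unit_rows(_as2d(z, "z"), "z")
        mixed = momentum * self.vectors[idx] + (1.0 - momentum) * z
        self.vectors[idx] = mixed / np.linalg.norm(mixed, axis=1,
                                                   keepdims=True)


def estimate_partition_constant(bank: MemoryBank, z: np.ndarray,
                                tau: float, sample_size: int = 256,
                                seed: int = 0) -> float:
    """One-off Monte Carlo estimate of the normalisation constant Z.

    Z is estimated as ``N * mean(exp(u . z / tau))`` over a seeded
    subsample of bank entries, then frozen by the caller. A stand-in for a
    constant the objective's definition leaves unspecified; an explicit Z
    can always be supplied instead.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(bank)
    take = min(sample_size, n)
    idx = rng.choice(n, size=take, replace=False)
    sims = bank.vectors[idx] @ np.asarray(z, dtype=float).T / tau
    return float(len(bank) * np.mean(np.exp(sims)))


def instance_recognition_loss(
    z: np.ndarray,
    positive_indices,
    bank: MemoryBank,
    n_negatives: int = 4096,
    tau: float = 0.07,
    partition_z: float | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Instance-recognition NCE loss against a memory bank.

    With ``h(u) = (e^{u.z/tau}/Z) / (e^{u.z/tau}/Z + m/N)``, the per-image
    loss is ``-log h(v) - sum_j log(1 - h(v_j))`` over ``m`` uniformly
    sampled negatives; returns ``(batch-mean loss, Z used)`` so the caller
    can freeze Z across iterations.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    z = _unit_rows(_as2d(z, "z"), "z")
    idx = np.atleast_1d(np.asarray(positive_indices, dtype=int))
    if len(idx) != len(z):
        raise ValueError("one positive index per embedding required")
    n = len(bank)
    m = int(n_negatives)
    if m < 1 or m > n:
        raise ValueError("need 1 <= n_negatives <= bank size")
    if partition_z is None:
        partition_z = estimate_partition_constant(bank, z, tau, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    def h(u: np.ndarray, zi: np.ndarray) -> np.ndarray:
        score = np.exp(u @ zi / tau) / partition_z
        return score / (score + m / n)

    losses = []
    for i in range(len(z)):
        pos = h(bank.vectors[idx[i]][None], z[i])[0]
        neg_idx = rng.choice(n, size=m, replace=False)
        neg = h(bank.vectors[neg_idx], z[i])
        losses.append(-np.log(pos) - np.sum(np.log1p(-neg)))
    return float(np.mean(losses)), float(partition_z)


class EmbeddingQueue:
    """FIFO queue of negative keys for momentum-contrast training."""

    def __init__(self, keys: np.ndarray):
        keys = _as2d(keys, "queue")
        if len(keys) == 0:
            raise ValueError("negative queue must be non-empty")
        self.keys = _unit_rows(keys, "queue")

    def __len__(self) -> int:
        return len(self.keys)

    def enqueue_dequeue(self, new_keys: np.ndarray) -> None:
        new = _unit_rows(_as2d(new_keys, "new_keys"), "new_keys")
        self.keys = np.vstack([self.keys, new])[len(new):]


def moco_loss(v: np.ndarray, k0: np.ndarray, queue: EmbeddingQueue,
              tau: float = 0.2) -> float:
    """InfoNCE over the positive key and the queued negatives.

    ``-log( e^{v.k0/tau} / (e^{v.k0/tau} + sum_i e^{v.k_i/tau}) )``,
    averaged over the batch.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if len(queue) == 0:
        raise ValueError("empty negative queue")
    v = _unit_rows(_as2d(v, "v"), "v")
    k0 = _unit_rows(_as2d(k0, "k0"), "k0")
    if v.shape != k0.shape:
        raise ValueError("v and k0 must have equal shapes")
    pos = (v * k0).sum(axis=1) / tau                      # (B,)
    neg = v @ queue.keys.T / tau                          # (B, K)
    logits = np.hstack([pos[:, None], neg])
    return float(np.mean(logsumexp(logits, axis=1) - pos))


def momentum_update(theta_k: np.ndarray, theta_q: np.ndarray,
                    momentum: float = 0.999) -> np.ndarray:
    """Key-encoder parameter update theta_k <- m theta_k + (1-m) theta_q."""
    theta_k = np.asarray(theta_k, dtype=float)
    theta_q = np.asarray(theta_q, dtype=float)
    if theta_k.shape != theta_q.shape:
        raise ValueError("parameter shapes differ")
    if not 0.0 <= momentum <= 1.0:
        raise ValueError("momentum must be in [0, 1]")
    return momentum * theta_k + (1.0 - momentum) * theta_q


# -- batch contrastive methods ----------------------------------------------

def simclr_loss(z1: np.ndarray, z2: np.ndarray, tau: float = 0.1) -> float:
    """NT-Xent over a batch of paired augmentations.

    For each of the 2N embeddings the loss is
    ``-log( e^{z.z'/tau} / sum_{i != anchor} e^{z.z_i/tau} )`` with z' its
    partner; the 2N per-anchor losses are averaged.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    z1 = _unit_rows(_as2d(z1, "z1"), "z1")
    z2 = _unit_rows(_as2d(z2, "z2"), "z2")
    if z1.shape != z2.shape:
        raise ValueError("paired views must have equal shapes")
    n = len(z1)
    if n < 2:
        raise ValueError("batch size must be >= 2")
    z = np.vstack([z1, z2])                     # (2N, d)
    sim = z @ z.T / tau
    np.fill_diagonal(sim, -np.inf)              # exclude the anchor itself
    partner = np.concatenate([np.arange(n, 2 * n), np.arange(n)])
    pos = sim[np.arange(2 * n), partner]
    return float(np.mean(logsumexp(sim, axis=1) - pos))


def simsiam_loss(p1: np.ndarray, p2: np.ndarray,
                 z1: np.ndarray, z2: np.ndarray) -> float:
    """Symmetric negative cosine similarity, in [-1, 1].

    The stop-gradient on z1/z2 is a gradient-flow contract and does not
    change the value.
    """
    p1, p2 = _as2d(p1, "p1"), _as2d(p2, "p2")
    z1, z2 = _as2d(z1, "z1"), _as2d(z2, "z2")
    if not (p1.shape == p2.shape == z1.shape == z2.shape):
        raise ValueError("all four embedding blocks must share a shape")

    def cos(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return (a * b).sum(axis=1) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))

    return float(np.mean(-0.5 * (cos(z1, p2) + cos(z2, p1))))


def barlow_twins_loss(z1: np.ndarray, z2: np.ndarray,
                      lam: float = 0.0051, center: bool = False) -> float:
    """Redundancy-reduction loss on the twin cross-correlation matrix.

    ``C_ij = sum_b z1_{b,i} z2_{b,j} / sqrt(sum_b z1_{b,i}^2
    sum_b z2_{b,j}^2)``; the loss drives C toward the identity:
    ``sum_i (1 - C_ii)^2 + lam * sum_{i != j} C_ij^2``. ``center=True``
    subtracts the per-dimension batch mean first (the variant used by the
    method's reference implementation).
    """
    z1, z2 = _as2d(z1, "z1"), _as2d(z2, "z2")
    if z1.shape != z2.shape:
        raise ValueError("paired views must have equal shapes")
    if len(z1) < 2:
        raise ValueError("batch size must be >= 2")
    if center:
        z1 = z1 - z1.mean(axis=0)
        z2 = z2 - z2.mean(axis=0)
    n1 = np.sqrt((z1**2).sum(axis=0))
    n2 = np.sqrt((z2**2).sum(axis=0))
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("zero-norm embedding dimension")
    c = (z1.T @ z2) / np.outer(n1, n2)
    on_diag = np.sum((1.0 - np.diag(c)) ** 2)
    off_diag = np.sum(c**2) - np.sum(np.diag(c) ** 2)
    return float(on_diag + lam * off_diag)


def vicreg_loss(z1: np.ndarray, z2: np.ndarray,
                sim_coeff: float = 25.0, std_coeff: float = 25.0,
                cov_coeff: float = 1.0, eps: float = 1e-4) -> float:
    """Variance-invariance-covariance regularisation loss.

    Three terms: invariance (mean squared distance between the views),
    variance (hinge keeping each dimension's batch standard deviation
    above 1) and covariance (off-diagonal covariance pulled to zero,
    scaled by the dimension). Coefficients (25, 25, 1) are the method's
    customary defaults, not values from this package's source data.
    """
    z1, z2 = _as2d(z1, "z1"), _as2d(z2, "z2")
    if z1.shape != z2.shape:
        raise ValueError("paired views must have equal shapes")
    n, d = z1.shape
    if n < 2:
        raise ValueError("batch size must be >= 2")
    invariance = float(np.mean((z1 - z2) ** 2))

    def variance_term(z: np.ndarray) -> float:
        std = np.sqrt(z.var(axis=0) + eps)
        return float(np.mean(np.maximum(0.0, 1.0 - std)))

    def covariance_term(z: np.ndarray) -> float:
        zc = z - z.mean(axis=0)
        cov = (zc.T @ zc) / (n - 1)
        return float((np.sum(cov**2) - np.sum(np.diag(cov) ** 2)) / d)

    return (sim_coeff * invariance
            + std_coeff * 0.5 * (variance_term(z1) + variance_term(z2))
            + cov_coeff * 0.5 * (covariance_term(z1) + covariance_term(z2)))
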