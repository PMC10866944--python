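"""STAPLE label fusion: EM estimation of a consensus segmentation.

Simultaneous Truth and Performance Level Estimation treats each of K rater
segmentations as a noisy observation of an unknown true binary segmentation,
characterized by per-rater sensitivity p_k and specificity q_k.  The EM
iteration alternates

  E-step:  W_i = a_i / (a_i + b_i), with
           a_i = prior * prod_k p_k^{d_ik} (1-p_k)^{1-d_ik}
           b_i = (1-prior) * prod_k (1-q_k)^{d_ik} q_k^{1-d_ik}
  M-step:  p_k = sum_i W_i d_ik / sum_i W_i
           q_k = sum_i (1-W_i)(1-d_ik) / sum_i (1-W_i)

until the performance parameters stop moving.  Multi-label fusion runs the
binary algorithm one-vs-rest per tumor label and assigns each voxel the
label with the highest posterior when that beats the implied background
posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TUMOR_LABELS = (1, 2, 4)
#: deterministic tie-break priority when posteriors tie exactly
LABEL_PRIORITY = (4, 1, 2)


@dataclass
class RaterPerformance:
    sensitivity: np.ndarray  # p_k per rater
    specificity: np.ndarray  # q_k per rater
    iterations: int
    converged: bool
    trace: list[dict] = field(default_factory=list)  # per-iteration p, q, log-likelihood


def _observed_ll(d: np.ndarray, p: np.ndarray, q: np.ndarray, prior: np.ndarray) -> float:
    """Observed-data log-likelihood sum_i log(a_i + b_i); the quantity EM
    guarantees to be non-decreasing across iterations."""
    eps = 1e-12
    la = np.log(prior + eps) + (np.log(p + eps)[:, None] * d + np.log(1 - p + eps)[:, None] * (1 - d)).sum(axis=0)
    lb = np.log(1 - prior + eps) + (np.log(1 - q + eps)[:, None] * d + np.log(q + eps)[:, None] * (1 - d)).sum(axis=0)
    return float(np.logaddexp(la, lb).sum())


def staple_binary(
    masks: np.ndarray | list[np.ndarray],
    tol: float = 1e-7,
    max_iter: int = 100,
    prior: float | np.ndarray | None = None,
    init_p: float = 0.99999,
    init_q: float = 0.99999,
    keep_trace: bool = False,
) -> tuple[np.ndarray, RaterPerformance]:
    """Binary STAPLE over K aligned rater masks.

    Returns the voxelwise posterior probability of the true segmentation
    (same shape as one mask) and the estimated rater performances.
    ``prior`` may be a scalar or a per-voxel array; the default is the
    per-voxel mean of the rater masks.  A spatial prior anchors the EM at
    the agreement regions — with a scalar (low) prior and only two raters
    the EM collapses to the raters' intersection, which systematically
    under-segments.
    """
    stack = np.stack([np.asarray(m, dtype=bool) for m in masks])
    k = stack.shape[0]
    if k < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    shape = stack.shape[1:]
    d = stack.reshape(k, -1).astype(np.float64)
    if prior is None:
        prior = d.mean(axis=0)
    else:
        prior = np.asarray(prior, dtype=np.float64)
        prior = np.broadcast_to(prior.reshape(-1) if prior.ndim else prior, (d.shape[1],))
    prior = np.clip(prior, 1e-6, 1 - 1e-6)
    p = np.full(k, init_p)
    q = np.full(k, init_q)
    eps = 1e-12
    w = prior.copy()
    trace: list[dict] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for numerical safety
        la = np.log(prior + eps) + (np.log(p + eps)[:, None] * d + np.log(1 - p + eps)[:, None] * (1 - d)).sum(axis=0)
        lb = np.log(1 - prior + eps) + (np.log(1 - q + eps)[:, None] * d + np.log(q + eps)[:, None] * (1 - d)).sum(axis=0)
        m = np.maximum(la, lb)
        a, b = np.exp(la - m), np.exp(lb - m)
        w = a / (a + b)
        # M-step
        wsum = w.sum()
        nsum = (1.0 - w).sum()
        p_new = (d * w).sum(axis=1) / max(wsum, eps)
        q_new = ((1 - d) * (1 - w)).sum(axis=1) / max(nsum, eps)
        if keep_trace:
            trace.append({"p": p_new.copy(), "q": q_new.copy(),
                          "ll": _observed_ll(d, p_new, q_new, prior)})
        delta = np.abs(p_new - p).sum() + np.abs(q_new - q).sum()
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(f"STAPLE did not converge in {max_iter} iterations", RuntimeWarning)
    perf = RaterPerformance(sensitivity=p, specificity=q, iterations=it, converged=converged, trace=trace)
    return w.reshape(shape), perf


def _union_bbox(stack: np.ndarray) -> tuple[slice, ...] | None:
    union = stack.any(axis=0)
    if not union.any():
        return None
    idx = np.nonzero(union)
    return tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)


def staple_multilabel(
    label_volumes: list[np.ndarray],
    labels: tuple[int, ...] = TUMOR_LABELS,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> tuple[np.ndarray, dict[int, RaterPerformance]]:
    """One-vs-rest STAPLE fusion of K label volumes into a consensus labeling.

    Each voxel receives the tumor label with the highest posterior, provided
    that posterior exceeds the implied background posterior 1 - max_label W;
    ties break by the fixed priority 4 > 1 > 2.  Restricting EM to the
    bounding box of rater-positive voxels changes nothing outside it (all
    raters agree on background there).
    """
    arrs = [np.asarray(v) for v in label_volumes]
    if len(arrs) < 2:
        raise ValueError("STAPLE fusion needs at least 2 rater volumes")
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError("rater volumes must share geometry")
    stack = np.stack(arrs)
    bbox = _union_bbox(stack != 0)
    fused = np.zeros(shape, dtype=np.int16)
    performances: dict[int, RaterPerformance] = {}
    if bbox is None:
        return fused, performances
    sub = stack[(slice(None),) + bbox]
    posteriors = {}
    for lab in labels:
        masks = sub == lab
        if not masks.any():
            posteriors[lab] = np.zeros(sub.shape[1:])
            continue
        w, perf = staple_binary(masks, tol=tol, max_iter=max_iter)
        posteriors[lab] = w
        performances[lab] = perf
    # priority-ordered stack so argmax ties resolve 4 > 1 > 2
    ordered = [posteriors[lab] for lab in LABEL_PRIORITY if lab in labels]
    order_labels = [lab for lab in LABEL_PRIORITY if lab in labels]
    post = np.stack(ordered)
    best = post.argmax(axis=0)
    best_w = np.take_along_axis(post, best[None], axis=0)[0]
    assign = np.where(best_w > 1.0 - best_w, np.array(order_labels, dtype=np.int16)[best], 0).astype(np.int16)
    fused[bbox] = assign
    return fused, performances
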