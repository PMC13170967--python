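"""Principal components of pedigree structure via randomized SVD.

The numerator relationship matrix factors as A = L L' with L the
pedigree Cholesky factor, so the principal components of the (column-
centred) A are obtained from a singular value decomposition of the
centred L — without ever forming A. For large pedigrees a randomized
sketch (Gaussian test matrix, oversampling 10, two power iterations)
reduces the SVD to a small dense problem; with a fixed seed the scores
are bit-reproducible.

Scores are left singular vectors scaled by singular values, one row per
animal, and can be annotated with cohort fields (year of birth, colour
group, show-breeding score, tested status) for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import Pedigree, show_breeding_score


@dataclass
class PCAResult:
    scores: np.ndarray  # n x k
    singular_values: np.ndarray
    seed: int
    oversampling: int
    power_iters: int


def randomized_pc_scores(
    L: sparse.spmatrix,
    k: int = 2,
    seed: int = 0,
    oversampling: int = 10,
    power_iters: int = 2,
    center: bool = True,
    tol: float | None = 1e-8,
) -> PCAResult:
    """Top-k principal-component scores of the pedigree relationship
    structure from its Cholesky factor.

    The columns of L are centred (equivalent to double-centring A up to
    rank-one terms), sketched with a seeded Gaussian test matrix with
    ``power_iters`` subspace (power) iterations, then refined with
    further power iterations until the top-k subspace moves by less
    than ``tol`` radians (``tol=None`` disables refinement and gives
    the fixed-iteration sketch). ``k`` larger than the centred rank is
    truncated with a warning. Fixed seed, bit-reproducible output.
    """
    import warnings

    n = L.shape[0]
    rank_cap = max(n - (1 if center else 0), 0)
    if k > rank_cap:
        warnings.warn(f"k={k} exceeds centred rank {rank_cap}; truncating")
        k = rank_cap
    rng = np.random.default_rng(seed)
    L = sparse.csr_matrix(L)
    col_means = np.asarray(L.mean(axis=0)).ravel() if center else np.zeros(L.shape[1])
    ones = np.ones(n)

    def mult(B: np.ndarray) -> np.ndarray:  # (Lc) @ B
        return L @ B - np.outer(ones, col_means @ B)

    def mult_t(B: np.ndarray) -> np.ndarray:  # (Lc)' @ B
        return L.T @ B - np.outer(col_means, ones @ B)

    p = min(k + oversampling, min(L.shape))
    Omega = rng.standard_normal((L.shape[1], p))
    Y = mult(Omega)
    Q, _ = np.linalg.qr(Y)

    def expand(Qm):
        B = mult_t(Qm).T  # p x m
        Ub, s, _ = np.linalg.svd(B, full_matrices=False)
        return Qm @ Ub, s

    U, s = None, None
    prev_topk = None
    max_power = max(power_iters, 60)
    for it in range(max_power + 1):
        U, s = expand(Q)
        # adaptive refinement: keep powering until the top-k subspace has
        # stabilized (the spectra of pedigree relationship matrices decay
        # slowly, so a fixed small iteration count is not reliably accurate)
        if it >= power_iters:
            if tol is None:
                break
            if prev_topk is not None:
                from scipy.linalg import subspace_angles

                if np.max(subspace_angles(U[:, :k], prev_topk)) < tol:
                    break
            prev_topk = U[:, :k].copy()
        Z = mult_t(Q)
        Qz, _ = np.linalg.qr(Z)
        Y = mult(Qz)
        Q, _ = np.linalg.qr(Y)
    # deterministic sign: largest-magnitude loading positive
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] *= -1
    scores = U[:, :k] * s[:k]
    return PCAResult(
        scores=scores,
        singular_values=s[:k].copy(),
        seed=seed,
        oversampling=oversampling,
        power_iters=power_iters,
    )


def annotate_scores(
    pca: PCAResult, ped: Pedigree, tested_ids=None, historic_before: int = 2016
) -> pd.DataFrame:
    """Join PC scores with cohort fields for plotting.

    Adds year of birth, colour group, show-breeding score, a tested
    flag and a "historic" flag for dogs born before ``historic_before``.
    """
    if pca.scores.shape[0] != len(ped):
        raise ValueError(
            f"scores rows ({pca.scores.shape[0]}) do not match pedigree size ({len(ped)})"
        )
    tested = set(tested_ids or ())
    df = pd.DataFrame(
        pca.scores, columns=[f"PC{j + 1}" for j in range(pca.scores.shape[1])]
    )
    df.insert(0, "id", ped.ids)
    df["yob"] = [r.dob.year if r.dob else np.nan for r in ped.records]
    df["colour_group"] = [r.colour_group for r in ped.records]
    df["SB"] = [show_breeding_score(ped, r.id) for r in ped.records]
    df["tested"] = [r.id in tested for r in ped.records]
    df["historic"] = df["yob"] < historic_before
    return df
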