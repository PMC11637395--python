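"""The normal hyperplane S and orthogonal projection onto it.

The latent codes of all N normal training images, together with the origin,
span a linear subspace S of the latent space (the "normal hyperplane"; the
origin belongs to it because the subspace is the span of the points). An
input latent is "virtually normalized" by dropping the perpendicular from it
onto S; the foot of that perpendicular, z0, is the unique Euclidean-nearest
point of S.

The basis is computed by a column-pivoted thin QR factorization of the
(latent_dim x n_train) matrix of training latents, with directions whose
R-diagonal magnitude falls below ``rank_tol`` times the largest dropped, so
rank-deficient training sets reduce cleanly to their numerical rank. The
factorization is performed in memory; this caps the practical training-set
size but removes any need for out-of-core machinery at the scales this
package targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DegeneracyError, InputError


@dataclass
class NormalBasis:
    """Orthonormal basis of the span of normal training latents.

    Attributes
    ----------
    Q
        ``(latent_dim, r)`` matrix with orthonormal columns.
    r
        Numerical rank retained.
    n_train
        Number of training latents the basis was built from.
    rank_tol
        Relative R-diagonal threshold used to fix ``r``.
    model_hash
        Optional SHA-256 of the generating flow model, used to detect
        model/basis mismatches at enhancement time.
    """

    Q: np.ndarray
    r: int
    n_train: int
    rank_tol: float
    model_hash: str = ""

    @property
    def latent_dim(self) -> int:
        return self.Q.shape[0]

    def save(self, path) -> None:
        meta = {
            "r": int(self.r),
            "n_train": int(self.n_train),
            "rank_tol": float(self.rank_tol),
            "model_hash": self.model_hash,
        }
        with open(path, "wb") as fh:
            np.savez(fh, Q=self.Q,
                     __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "NormalBasis":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            return cls(Q=data["Q"], **meta)


def build_hyperplane(z_training: np.ndarray, rank_tol: float = 1e-10,
                     model_hash: str = "") -> NormalBasis:
    """Build the normal-hyperplane basis from training latents.

    Parameters
    ----------
    z_training
        ``(latent_dim, n_train)`` matrix whose columns are the latent codes of
        the normal training images. ``n_train`` must be strictly smaller than
        ``latent_dim`` — if the latents span the whole space the perpendicular
        projection collapses to the identity and enhancement degenerates.
    rank_tol
        Relative threshold below which a pivoted-QR diagonal is treated as
        numerically zero.
    """
    z_training = np.asarray(z_training, dtype=np.float64)
    if z_training.ndim != 2:
        raise InputError(f"expected a 2-D latent matrix, got ndim={z_training.ndim}")
    if not np.all(np.isfinite(z_training)):
        raise InputError("training latents contain non-finite values")
    latent_dim, n_train = z_training.shape
    if n_train < 1:
        raise InputError("need at least one training latent")
    if n_train >= latent_dim:
        raise DegeneracyError(
            f"n_train={n_train} >= latent_dim={latent_dim}: the hyperplane "
            "spans the whole latent space and projection is the identity"
        )
    q, rmat, _ = scipy.linalg.qr(z_training, mode="economic", pivoting=True)
    diag = np.abs(np.diag(rmat))
    if diag.size == 0 or diag[0] == 0.0:
        rank = 0
    else:
        rank = int(np.sum(diag > rank_tol * diag[0]))
    return NormalBasis(Q=np.ascontiguousarray(q[:, :rank]), r=rank,
                       n_train=n_train, rank_tol=rank_tol, model_hash=model_hash)


def project_to_hyperplane(z_input: np.ndarray, basis: NormalBasis) -> np.ndarray:
    """Perpendicular projection z0 = Q (Q^T z) of a latent onto S.

    z0 is the unique nearest point of S in Euclidean distance; the residual
    ``z_input - z0`` is orthogonal to every basis vector.
    """
    z_input = np.asarray(z_input, dtype=np.float64)
    flat = z_input.ravel()
    if flat.size != basis.latent_dim:
        raise InputError(
            f"latent length {flat.size} != basis dimension {basis.latent_dim}"
        )
    z0 = basis.Q @ (basis.Q.T @ flat)
    return z0.reshape(z_input.shape)
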