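"""De-novo mutational signature extraction (NMF) and exposure refitting
against a known signature catalog.

The 96-channel convention and ordering come from :mod:`somavar.spectrum`
(class-major, pyrimidine-referenced). Catalog TSVs have one row per channel
and one column per signature; profiles are normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import cosine as cosine_distance

from .errors import SignatureError
from .spectrum import CHANNELS96

_EPS = 1e-12


@dataclass
class SignatureCatalog:
    """Named 96-channel signature profiles, each summing to one."""

    profiles: pd.DataFrame  # index CHANNELS96, one column per signature

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise SignatureError("catalog profiles must be non-negative")
        if list(self.profiles.index) != list(CHANNELS96):
            self.profiles = self.profiles.reindex(list(CHANNELS96))
            if self.profiles.isna().any().any():
                raise SignatureError("catalog rows must cover the 96 channels")
        sums = self.profiles.sum(axis=0)
        if (sums <= 0).any():
            raise SignatureError("catalog contains an all-zero profile")
        self.profiles = self.profiles / sums

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    def __len__(self) -> int:
        return self.profiles.shape[1]

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(profiles=df)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.profiles.to_csv(path, sep="\t", index_label="channel")


def synthetic_catalog(
    n_signatures: int = 3, seed: int = 0, sparsity: float = 0.8
) -> SignatureCatalog:
    """Random sparse catalog for simulations and tests (synthetic stand-in for
    a curated signature database, which this package does not ship)."""
    rng = np.random.default_rng(seed)
    profiles = {}
    for i in range(n_signatures):
        weights = rng.gamma(0.5, size=96)
        mask = rng.random(96) < sparsity
        weights[mask] = 0.0
        if weights.sum() == 0:
            weights[rng.integers(96)] = 1.0
        profiles[f"S{i + 1}"] = weights / weights.sum()
    return SignatureCatalog(pd.DataFrame(profiles, index=list(CHANNELS96)))


@dataclass
class NmfResult:
    profiles: pd.DataFrame  # 96 x k, column-normalized
    contributions: pd.DataFrame  # k x n_samples
    reconstruction_error: float  # Frobenius norm of the residual
    restart_seed: int  # seed of the winning restart
    objective_path: list[float]  # per-iteration objective of the winning run


def _mu_nmf(
    V: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative-update NMF minimizing the Frobenius error.

    The objective is checked to be non-increasing at every iteration (a small
    relative slack absorbs floating-point noise).
    """
    m, n = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(_EPS, 1.0, size=(m, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n)) * scale
    prev = np.linalg.norm(V - W @ H)
    path = [float(prev)]
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        err = np.linalg.norm(V - W @ H)
        if err > prev * (1 + 1e-9) + 1e-12:
            raise AssertionError("NMF objective increased between iterations")
        path.append(float(err))
        if prev - err < tol * max(prev, 1.0):
            break
        prev = err
    return W, H, path


def extract_signatures(
    counts96,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> NmfResult:
    """Extract ``k`` de-novo signatures from per-sample 96-channel counts.

    ``counts96`` is a DataFrame (index = 96 channels, one column per sample)
    or an array of shape (96, n_samples). The best of ``n_restarts`` random
    restarts (Frobenius error) is kept; its restart seed is reported.
    """
    if isinstance(counts96, pd.DataFrame):
        V = counts96.reindex(list(CHANNELS96)).to_numpy(dtype=float)
        samples = list(counts96.columns)
    else:
        V = np.asarray(counts96, dtype=float)
        samples = [f"sample{i}" for i in range(V.shape[1])]
    if V.shape[0] != 96:
        raise SignatureError("counts matrix must have 96 channel rows")
    if (V < 0).any():
        raise SignatureError("counts must be non-negative")
    if k > V.shape[1]:
        raise SignatureError(f"k={k} exceeds number of samples {V.shape[1]}")

    best: tuple[float, np.ndarray, np.ndarray, int, list[float]] | None = None
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    for restart_seed in seeds:
        rng = np.random.default_rng(int(restart_seed))
        W, H, path = _mu_nmf(V, k, rng, max_iter, tol)
        if best is None or path[-1] < best[0]:
            best = (path[-1], W, H, int(restart_seed), path)
    err, W, H, win_seed, path = best
    col_sums = W.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    W_norm = W / col_sums
    H_scaled = H * col_sums[:, None]
    names = [f"denovo{i + 1}" for i in range(k)]
    return NmfResult(
        profiles=pd.DataFrame(W_norm, index=list(CHANNELS96), columns=names),
        contributions=pd.DataFrame(H_scaled, index=names, columns=samples),
        reconstruction_error=float(err),
        restart_seed=win_seed,
        objective_path=path,
    )


@dataclass
class ExposureFit:
    """Per-signature exposure fractions plus unexplained residual mass."""

    exposures: pd.Series  # one entry per catalog signature, >= 0
    unknown_fraction: float
    reconstruction_error: float  # cosine distance truth vs reconstruction

    def __post_init__(self) -> None:
        total = float(self.exposures.sum()) + self.unknown_fraction
        assert abs(total - 1.0) < 1e-9, "exposures + unknown must sum to 1"


def fit_exposures(
    counts96, catalog: SignatureCatalog, min_exposure: float = 0.06
) -> ExposureFit:
    """Refit a 96-channel count vector against a known catalog.

    Non-negative least squares on the normalized count vector; signatures
    whose exposure falls below ``min_exposure`` are zeroed and the fit re-run
    on the survivors until stable (deconstructSigs-style pruning).
    """
    if isinstance(counts96, pd.Series):
        v = counts96.reindex(list(CHANNELS96)).to_numpy(dtype=float)
    else:
        v = np.asarray(counts96, dtype=float)
    if v.shape != (96,):
        raise SignatureError("count vector must have 96 channels")
    if v.sum() <= 0:
        raise SignatureError("all-zero count vector")
    v = v / v.sum()
    P = catalog.profiles.to_numpy(dtype=float)
    names = catalog.names

    active = list(range(len(names)))
    coef = np.zeros(len(names))
    while active:
        sol, _ = nnls(P[:, active], v)
        coef = np.zeros(len(names))
        coef[active] = sol
        below = [i for i in active if 0 < coef[i] < min_exposure]
        if not below:
            break
        active = [i for i in active if coef[i] >= min_exposure]
    recon = P @ coef
    err = float(cosine_distance(v, recon)) if recon.sum() > 0 else 1.0
    total = coef.sum()
    if total > 1.0:  # NNLS overshoot; exposures are fractions of the spectrum
        coef = coef / total
        total = 1.0
    return ExposureFit(
        exposures=pd.Series(coef, index=names, name="exposure"),
        unknown_fraction=float(1.0 - total),
        reconstruction_error=err,
    )
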