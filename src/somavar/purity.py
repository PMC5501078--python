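"""Tumor cellularity estimation from somatic mutant allele fractions.

Model: somatic variants are clonal, heterozygous and diploid, so their
expected MAF is purity/2 and the estimate is twice a central statistic of the
MAF distribution. The default statistic is the mode of a Gaussian-kernel
density (robust to a subclonal low-MAF tail); the median is also available.
Copy-number aware or subclonal decomposition is explicitly out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import gaussian_kde

from .errors import InsufficientDataError

MIN_MAFS = 20


@dataclass(frozen=True)
class PurityEstimate:
    estimate: float  # in (0, 1]
    n_variants: int
    method: str  # mode | median
    bandwidth: float


def estimate_purity(
    somatic_mafs: Iterable[float],
    method: str = "mode",
    maf_window: tuple[float, float] = (0.05, 0.5),
    bandwidth: float = 0.03,
) -> PurityEstimate:
    """Estimate tumor purity as 2x the central MAF of clonal somatic variants.

    Only MAFs in ``(maf_window[0], maf_window[1]]`` are used; fewer than 20
    usable values raises :class:`InsufficientDataError` rather than returning
    a silent estimate.
    """
    if method not in ("mode", "median"):
        raise ValueError(f"method must be 'mode' or 'median', got {method!r}")
    mafs = np.asarray([m for m in somatic_mafs if m is not None], dtype=float)
    lo, hi = maf_window
    usable = mafs[(mafs > lo) & (mafs <= hi)]
    if len(usable) < MIN_MAFS:
        raise InsufficientDataError(
            f"need >= {MIN_MAFS} MAFs in ({lo}, {hi}], got {len(usable)}"
        )
    if method == "median":
        central = float(np.median(usable))
    elif np.ptp(usable) < 1e-12:
        # degenerate (constant) sample: the mode is the constant itself
        central = float(usable[0])
    else:
        # gaussian_kde scales its bandwidth by the sample std; convert the
        # absolute kernel width into scipy's factor
        kde = gaussian_kde(usable, bw_method=bandwidth / usable.std(ddof=1))
        grid = np.arange(lo, hi + 1e-9, 5e-4)
        central = float(grid[np.argmax(kde(grid))])
    estimate = min(max(2.0 * central, 1e-9), 1.0)
    return PurityEstimate(
        estimate=estimate, n_variants=len(usable), method=method, bandwidth=bandwidth
    )
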