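"""Read-length and read-start distributions, and expected read benefits.

A read starting at position i with orientation o covers consecutive sites in
the read direction; its expected benefit U_{i,o} is the sum of the positional
scores it would cover, weighted by the probability (from the read-length
distribution) of reaching each of them:

    U_{i,1} = sum_{k >= 0} S_{i+k} * P(L >= k + 1),

the complementary-CDF (suffix-sum) form of the naive double sum over lengths.
The decision about a read is made after its first mu bases, whose benefit
S^mu_{i,o} (a fixed window sum) accrues whether or not the read is rejected.

Time is measured in base-translocation units (one base through the pore = one
unit). ``TimeModel`` carries the acquisition time alpha, the rejection-
effecting time rho, and the decision-fragment length mu.

Orientation convention throughout the package: index 0 = forward ('+'),
index 1 = reverse ('-').
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

FORWARD, REVERSE = 0, 1

DEFAULT_TRANSLOCATION_SPEED = 450.0  # nt per second


def mu_from_chunk(chunk_seconds: float, speed: float = DEFAULT_TRANSLOCATION_SPEED) -> int:
    """Decision-fragment length mu: basecalling chunk time x translocation speed."""
    return int(round(chunk_seconds * speed))


@dataclass(frozen=True)
class TimeModel:
    """Sequencing-process constants, all in base-translocation time units."""

    alpha: float = 300.0   # time to acquire a new read at a pore
    rho: float = 300.0     # time to effect a rejection
    mu: int = mu_from_chunk(0.8)  # initial bases read before the decision

    def __post_init__(self):
        if self.alpha < 0 or self.rho < 0 or self.mu < 1:
            raise ValueError("time constants must be non-negative (mu >= 1)")


@dataclass(frozen=True)
class ReadLengthDist:
    """Probability mass over integer read lengths with a truncated-normal prior.

    The prior is blended with the empirical histogram of observed full-length
    reads by effective-sample-size weighting: ``prior_weight`` acts as a
    pseudo-count of reads carrying the prior shape. Lengths are tracked
    exactly (per-length histogram) up to ``max_length``; longer observations
    are clipped.
    """

    prior_pmf: np.ndarray        # (max_length + 1,), index = length
    prior_weight: float = 100.0
    counts: np.ndarray = None    # cumulative per-length histogram
    n_obs: int = 0

    def __post_init__(self):
        if self.counts is None:
            object.__setattr__(self, "counts", np.zeros_like(self.prior_pmf))

    @classmethod
    def from_truncated_normal(
        cls,
        mean: float = 3000.0,
        sd: float = 1500.0,
        lower: int = 360,
        max_length: int = 20000,
        prior_weight: float = 100.0,
    ) -> "ReadLengthDist":
        """Discretized normal prior truncated to [lower, max_length]."""
        lengths = np.arange(max_length + 1)
        pmf = stats.norm.pdf(lengths, loc=mean, scale=sd)
        pmf[:lower] = 0.0
        total = pmf.sum()
        if total <= 0:
            raise ValueError("prior truncated-normal has no mass on the support")
        return cls(prior_pmf=pmf / total, prior_weight=prior_weight)

    @classmethod
    def point_mass(cls, length: int, max_length: int | None = None) -> "ReadLengthDist":
        pmf = np.zeros((max_length or length) + 1)
        pmf[length] = 1.0
        return cls(prior_pmf=pmf, prior_weight=1.0)

    @property
    def max_length(self) -> int:
        return len(self.prior_pmf) - 1

    @property
    def pmf(self) -> np.ndarray:
        total = self.prior_weight + self.n_obs
        if total <= 0:
            raise ValueError("length distribution has zero total weight")
        return (self.prior_weight * self.prior_pmf + self.counts) / total

    @property
    def mean(self) -> float:
        """lambda = E[L]."""
        pmf = self.pmf
        return float(np.arange(len(pmf)) @ pmf)

    @property
    def ccdf(self) -> np.ndarray:
        """tail[k] = P(L >= k + 1), k = 0 .. max_length - 1; non-increasing."""
        pmf = self.pmf
        tail = 1.0 - np.cumsum(pmf)
        np.maximum(tail[:-1], 0.0, out=tail[:-1])
        return tail[:-1]


def update_length_dist(dist: ReadLengthDist, observed_lengths) -> ReadLengthDist:
    """Fold observed full-length read lengths into the distribution.

    Only accepted (fully sequenced) reads should be fed in; rejected reads'
    observed lengths are an artifact of the decision point, not of the
    fragment-length process.
    """
    lengths = np.asarray(observed_lengths, dtype=np.int64)
    if lengths.size == 0:
        return dist
    if np.any(lengths < 1):
        raise ValueError("read lengths must be >= 1")
    clipped = np.minimum(lengths, dist.max_length)
    hist = np.bincount(clipped, minlength=dist.max_length + 1).astype(float)
    return replace(dist, counts=dist.counts + hist, n_obs=dist.n_obs + lengths.size)


@dataclass(frozen=True)
class ReadStartDist:
    """Distribution w_{i,o} of the next read's start position and orientation.

    Covers all contigs under management (possibly from several references);
    probabilities are normalized globally. The default is uniform, 1/(2N) for
    total length N. Empirical start counts are blended with the uniform prior
    by effective-sample-size weighting and smoothed with a boxcar window so
    unseen origins are never locked out.
    """

    contig_lengths: dict
    prior_weight: float = 100.0
    smooth_window: int = 2001
    counts: dict = None          # contig -> (2, N) float array
    n_obs: int = 0

    def __post_init__(self):
        if self.counts is None:
            object.__setattr__(
                self,
                "counts",
                {c: np.zeros((2, n)) for c, n in self.contig_lengths.items()},
            )

    @property
    def total_positions(self) -> int:
        return 2 * sum(self.contig_lengths.values())

    def probs(self) -> dict:
        """contig -> (2, N) start probabilities, summing to 1 globally."""
        uniform = 1.0 / self.total_positions
        total = self.prior_weight + self.n_obs
        out = {}
        for contig, cnt in self.counts.items():
            emp = cnt
            if self.smooth_window > 1 and self.n_obs > 0:
                kernel = np.ones(self.smooth_window) / self.smooth_window
                emp = np.empty_like(cnt)
                for o in (FORWARD, REVERSE):
                    sm = signal.convolve(cnt[o], kernel, mode="same", method="auto")
                    row_total = cnt[o].sum()
                    sm_total = sm.sum()
                    if sm_total > 0:
                        sm *= row_total / sm_total
                    emp[o] = sm
            out[contig] = (self.prior_weight * uniform + emp) / total
        return out


def update_start_dist(dist: ReadStartDist, observed_starts) -> ReadStartDist:
    """Fold observed (contig, position, orientation) read starts in.

    Orientation may be 0/1 (forward/reverse) or '+'/'-'.
    """
    counts = {c: a.copy() for c, a in dist.counts.items()}
    n_new = 0
    for contig, pos, orient in observed_starts:
        if contig not in counts:
            raise ValueError(f"unknown contig {contig!r}")
        if isinstance(orient, str):
            orient = FORWARD if orient == "+" else REVERSE
        n = dist.contig_lengths[contig]
        if not 0 <= pos < n:
            raise ValueError(f"start {pos} out of bounds for contig {contig!r} (length {n})")
        counts[contig][orient, pos] += 1.0
        n_new += 1
    return replace(dist, counts=counts, n_obs=dist.n_obs + n_new)


def _forward_benefit(scores: np.ndarray, tail: np.ndarray, circular: bool) -> np.ndarray:
    n = len(scores)
    nz = np.nonzero(tail)[0]
    if nz.size == 0:
        return np.zeros(n)
    tail = tail[: nz[-1] + 1]
    k = len(tail)
    s = scores
    if circular and k > 1:
        s = np.concatenate([scores, scores[: k - 1]])
    conv = signal.convolve(s, tail[::-1], method="auto")
    return conv[k - 1 : k - 1 + n]


def expected_benefit(
    scores: np.ndarray,
    dist: ReadLengthDist,
    orientation: int = FORWARD,
    circular: bool = False,
) -> np.ndarray:
    """Expected full-read benefit U_{i,o} for every start position i.

    Computed in the CCDF suffix-sum form, exactly equal to the naive double
    sum over read lengths. Reads running off the contig end truncate (no
    wraparound) unless ``circular`` is set.
    """
    scores = np.asarray(scores, dtype=float)
    tail = dist.ccdf
    if orientation == FORWARD:
        return _forward_benefit(scores, tail, circular)
    return _forward_benefit(scores[::-1], tail, circular)[::-1]


def mu_benefit(
    scores: np.ndarray,
    mu: int,
    orientation: int = FORWARD,
    circular: bool = False,
) -> np.ndarray:
    """Initial-fragment benefit S^mu_{i,o}: window sum of mu consecutive scores
    from i in the read direction, truncated at contig ends."""
    if mu < 1:
        raise ValueError("mu must be >= 1")
    scores = np.asarray(scores, dtype=float)
    if orientation == REVERSE:
        return mu_benefit(scores[::-1], mu, FORWARD, circular)[::-1]
    n = len(scores)
    if circular and mu > 1:
        ext = np.concatenate([scores, scores[: mu - 1]])
        cs = np.concatenate([[0.0], np.cumsum(ext)])
        idx = np.arange(n)
        return cs[idx + mu] - cs[idx]
    cs = np.concatenate([[0.0], np.cumsum(scores)])
    idx = np.arange(n)
    hi = np.minimum(idx + mu, n)
    return cs[hi] - cs[idx]


def approximate_benefit(
    scores: np.ndarray,
    dist: ReadLengthDist,
    knots: int,
    orientation: int = FORWARD,
    circular: bool = False,
) -> np.ndarray:
    """Expected benefit with the CCDF replaced by a piecewise-constant staircase.

    The exact CCDF is a step function with one run of constant value per
    distinct tail level; runs are merged into ``knots`` contiguous groups and
    each group replaced by its positional mean (which preserves the mean read
    length). With ``knots`` at least the number of runs the result is exact.
    The exact :func:`expected_benefit` remains the reference computation.
    """
    if knots < 1:
        raise ValueError("knots must be >= 1")
    scores = np.asarray(scores, dtype=float)
    tail = dist.ccdf
    nz = np.nonzero(tail)[0]
    if nz.size == 0:
        return np.zeros(len(scores))
    tail = tail[: nz[-1] + 1].copy()
    # run boundaries: indices where the staircase drops
    change = np.nonzero(np.diff(tail))[0] + 1
    run_starts = np.concatenate([[0], change])
    if knots >= len(run_starts):
        approx = tail
    else:
        run_bounds = np.concatenate([run_starts, [len(tail)]])
        groups = np.array_split(np.arange(len(run_starts)), knots)
        approx = np.empty_like(tail)
        for g in groups:
            lo, hi = run_bounds[g[0]], run_bounds[g[-1] + 1]
            approx[lo:hi] = tail[lo:hi].mean()
    if orientation == FORWARD:
        return _forward_benefit(scores, approx, circular)
    return _forward_benefit(scores[::-1], approx, circular)[::-1]


def length_dist_table(dist: ReadLengthDist, bin_width: int = 100) -> np.ndarray:
    """Two-column (length_bin_start, mass) summary for export."""
    pmf = dist.pmf
    n_bins = int(np.ceil(len(pmf) / bin_width))
    starts = np.arange(n_bins) * bin_width
    mass = np.add.reduceat(pmf, starts)
    return np.column_stack([starts, mass])
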