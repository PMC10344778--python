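"""Decision strategies maximizing expected benefit per unit sequencing time.

A strategy is a Boolean indicator over every (position, orientation) pair of
every contig: 1 means a read starting there is sequenced to completion, 0
means it is ejected after its first mu bases. Under start-probability field
w_{i,o}, full-read benefit U_{i,o}, initial-fragment benefit S^mu_{i,o} and
mean read length lambda, the objective is the ratio

    Ubar = sum w * S^mu  +  sum_{accepted} w * (U - S^mu)
    tbar = alpha + mu + rho + sum_{accepted} w * (lambda - mu - rho)

maximized over strategies. The optimum is a threshold set in the marginal
benefit-per-time ratio, so ranking candidates by (U - S^mu) / (lambda-mu-rho)
and scanning ranked prefixes attains the exhaustive maximum; with a single
shared length distribution this ordering coincides with ranking by the gain
U - S^mu itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from poreselect.read_model import FORWARD, REVERSE, TimeModel

logger = logging.getLogger(__name__)


@dataclass
class DecisionStrategy:
    """Boolean accept/reject indicators per (position, orientation) per contig.

    ``masks[contig]`` has shape (2, N): row 0 forward starts, row 1 reverse.
    """

    masks: dict
    step: int = 0
    ubar: float = float("nan")
    tbar: float = float("nan")
    ratio: float = float("nan")

    @property
    def size(self) -> int:
        """|S|: number of accepted (position, orientation) pairs."""
        return int(sum(m.sum() for m in self.masks.values()))

    def accepted_fraction(self, contig: str | None = None) -> float:
        if contig is not None:
            m = self.masks[contig]
            return float(m.sum() / m.size)
        tot = sum(m.size for m in self.masks.values())
        return self.size / tot

    @classmethod
    def accept_all(cls, contig_lengths: dict, step: int = 0) -> "DecisionStrategy":
        return cls(
            masks={c: np.ones((2, n), dtype=bool) for c, n in contig_lengths.items()},
            step=step,
        )

    @classmethod
    def reject_all(cls, contig_lengths: dict, step: int = 0) -> "DecisionStrategy":
        return cls(
            masks={c: np.zeros((2, n), dtype=bool) for c, n in contig_lengths.items()},
            step=step,
        )


def _lam_for(lam, contig: str) -> float:
    return lam[contig] if isinstance(lam, dict) else float(lam)


def objective(
    strategy: DecisionStrategy,
    u: dict,
    smu: dict,
    w: dict,
    time: TimeModel,
    lam,
) -> tuple[float, float, float]:
    """Average expected benefit, expected per-read time and their ratio.

    ``u``, ``smu`` and ``w`` map contig -> (2, N) arrays; ``w`` must be a
    probability field over all (position, orientation) pairs (uniform case:
    w = 1/(2N) everywhere). ``lam`` is the mean read length, a float or a
    per-contig dict. The initial-fragment benefit accrues at every position,
    accepted or not: rejected reads still deliver their first mu bases.
    """
    ubar = 0.0
    t_extra = 0.0
    for contig, mask in strategy.masks.items():
        wc = w[contig]
        ubar += float((wc * smu[contig]).sum())
        ubar += float((wc[mask] * (u[contig][mask] - smu[contig][mask])).sum())
        t_extra += float(wc[mask].sum()) * (_lam_for(lam, contig) - time.mu - time.rho)
    tbar = time.alpha + time.mu + time.rho + t_extra
    if tbar <= 0:
        raise ValueError(f"internal inconsistency: expected per-read time {tbar} <= 0")
    return ubar, tbar, ubar / tbar


def uniform_start_field(contig_lengths: dict) -> dict:
    """w = 1/(2N) for every (position, orientation) pair across all contigs."""
    total = 2 * sum(contig_lengths.values())
    return {c: np.full((2, n), 1.0 / total) for c, n in contig_lengths.items()}


def compute_strategy(
    u: dict,
    smu: dict,
    w: dict,
    time: TimeModel,
    lam,
    allowed: dict | None = None,
    forced: dict | None = None,
    step: int = 0,
) -> DecisionStrategy:
    """Optimal strategy by ranked-prefix search over marginal benefit/time.

    Candidates are ranked in decreasing order of marginal ratio
    (U - S^mu) / (lambda - mu - rho) — equivalently by the gain U - S^mu when
    all contigs share one length distribution — with ties broken by
    (contig order, position, orientation); ranked prefixes are scanned
    and the first maximizer of Ubar/tbar returned. Candidates whose inclusion
    cannot increase the expected time (lambda <= mu + rho) are always
    accepted: rejection would only waste time there.

    ``allowed`` (contig -> bool (2, N)) excludes candidates entirely (their
    indicator is forced to 0, e.g. outside ROI masks); ``forced`` pins
    candidates to 1 regardless of rank (e.g. coverage-gated windows that keep
    their initial accept state).
    """
    contigs = list(u.keys())
    rs, wgains, dts, free_idx = [], [], [], []
    base_b = 0.0
    base_t = time.alpha + time.mu + time.rho
    masks = {}
    for ci, contig in enumerate(contigs):
        uc, sc, wc = u[contig], smu[contig], w[contig]
        gain = uc - sc
        dt_unit = _lam_for(lam, contig) - time.mu - time.rho
        base_b += float((wc * sc).sum())
        allow = allowed[contig] if allowed is not None else np.ones_like(uc, dtype=bool)
        force = (forced[contig] if forced is not None else np.zeros_like(uc, dtype=bool)) & allow
        mask = force.copy()
        base_b += float((wc[force] * gain[force]).sum())
        base_t += float(wc[force].sum()) * dt_unit
        free = allow & ~force
        if dt_unit <= 0:
            # completing a read here is never slower than rejecting it
            mask |= free
            base_b += float((wc[free] * gain[free]).sum())
            base_t += float(wc[free].sum()) * dt_unit
        else:
            # candidates enumerated position-major so that a stable sort on
            # the marginal ratio breaks ties by (contig, position, orientation)
            pi, oi = np.nonzero(free.T)
            g = gain[oi, pi]
            rs.append(g / dt_unit)
            wgains.append(wc[oi, pi] * g)
            dts.append(wc[oi, pi] * dt_unit)
            free_idx.append((np.full(g.shape, ci), oi, pi))
        masks[contig] = mask

    ubar, tbar = base_b, base_t
    if wgains:
        r = np.concatenate(rs)
        order = np.argsort(-r, kind="stable")
        inc_b = np.concatenate(wgains)[order]
        inc_t = np.concatenate(dts)[order]
        cum_b = base_b + np.concatenate([[0.0], np.cumsum(inc_b)])
        cum_t = base_t + np.concatenate([[0.0], np.cumsum(inc_t)])
        ratios = cum_b / cum_t
        k_best = int(np.argmax(ratios))  # first maximizer: deterministic
        ubar, tbar = float(cum_b[k_best]), float(cum_t[k_best])
        if k_best > 0:
            take = order[:k_best]
            ci_all = np.concatenate([ix[0] for ix in free_idx])[take]
            oi_all = np.concatenate([ix[1] for ix in free_idx])[take]
            pi_all = np.concatenate([ix[2] for ix in free_idx])[take]
            for ci in np.unique(ci_all):
                sel = ci_all == ci
                masks[contigs[ci]][oi_all[sel], pi_all[sel]] = True

    strat = DecisionStrategy(masks=masks, step=step)
    strat.ubar, strat.tbar = ubar, tbar
    strat.ratio = ubar / tbar
    return strat


def merge_references(
    per_ref_u: list,
    per_ref_smu: list,
    per_ref_starts: list,
    time: TimeModel,
    per_ref_lam: list,
    weights: list | None = None,
    **kwargs,
) -> DecisionStrategy:
    """Common strategy across several references.

    Each reference contributes its benefit fields and its own start
    distribution; ``weights`` are the observed read-origin proportions of the
    references (default: proportional to each start distribution's observed
    read count, falling back to total reference length). All contig names
    must be globally unique. The result is one joint ranking and one global
    prefix optimum; per-reference masks are available in the returned
    strategy's ``masks``.
    """
    if not per_ref_u:
        raise ValueError("at least one reference is required")
    names = [c for u in per_ref_u for c in u]
    if len(set(names)) != len(names):
        raise ValueError("contig names must be unique across references")
    if weights is None:
        n_obs = [sd.n_obs for sd in per_ref_starts]
        if sum(n_obs) > 0:
            weights = [x + 1.0 for x in n_obs]  # +1: no reference locked out
        else:
            weights = [sum(sd.contig_lengths.values()) for sd in per_ref_starts]
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    u, smu, w, lam = {}, {}, {}, {}
    for ru, rs, sd, wt, rl in zip(per_ref_u, per_ref_smu, per_ref_starts, weights, per_ref_lam):
        probs = sd.probs()
        for contig in ru:
            u[contig] = ru[contig]
            smu[contig] = rs[contig]
            w[contig] = wt * probs[contig]
            lam[contig] = rl
    return compute_strategy(u, smu, w, time, lam, **kwargs)


def apply_roi_mask(contig_lengths: dict, rois: dict, flank: int) -> dict:
    """Allowed-start mask from regions of interest with oriented flanks.

    Reads must overlap an ROI to be useful, so acceptable forward starts for
    an ROI [start, end) extend ``flank`` bases upstream: [start - flank, end);
    acceptable reverse starts extend downstream: [start, end + flank).
    Positions outside all ROIs (plus flanks) are excluded from ranking and
    their indicators forced to 0. An empty ROI set yields a reject-all mask.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    allowed = {c: np.zeros((2, n), dtype=bool) for c, n in contig_lengths.items()}
    for contig, intervals in rois.items():
        if contig not in allowed:
            raise ValueError(f"ROI contig {contig!r} not among references")
        n = contig_lengths[contig]
        for start, end in intervals:
            if start >= end:
                raise ValueError(f"malformed ROI interval [{start}, {end}) on {contig!r}")
            if start < 0 or end > n:
                raise ValueError(f"ROI [{start}, {end}) outside contig {contig!r} bounds")
            allowed[contig][FORWARD, max(0, start - flank): end] = True
            allowed[contig][REVERSE, start: min(n, end + flank)] = True
    return allowed


def coverage_gate(
    coverage: dict,
    window: int = 20000,
    min_coverage: float = 5.0,
) -> dict:
    """Forced-accept mask for windows below the update gating threshold.

    Strategy updates for a window apply only once it has reached the minimum
    mean coverage (default >= 5x in 20-kb windows); until then the window
    keeps its initial accept state. Returns contig -> bool (2, N), True where
    the window is still forced to accept.
    """
    forced = {}
    for contig, depth in coverage.items():
        n = len(depth)
        f = np.zeros(n, dtype=bool)
        for lo in range(0, n, window):
            hi = min(lo + window, n)
            if depth[lo:hi].mean() < min_coverage:
                f[lo:hi] = True
        forced[contig] = np.broadcast_to(f, (2, n)).copy()
    return forced


def decide(mapping, strategy: DecisionStrategy) -> bool:
    """Accept (True) or reject (False) a read given its best mapping.

    ``mapping`` is (contig, position, orientation) with orientation 0/1 or
    '+'/'-', or None for an unmapped / no-sequence read (always rejected).
    A mapping to a contig absent from the strategy is rejected with a warning.
    """
    if mapping is None:
        return False
    contig, pos, orient = mapping
    if isinstance(orient, str):
        orient = FORWARD if orient == "+" else REVERSE
    mask = strategy.masks.get(contig)
    if mask is None:
        logger.warning("decide: contig %r absent from strategy; rejecting", contig)
        return False
    return bool(mask[orient, pos])
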