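"""Evaluation statistics for runs: coverage, resolution, evenness, abundance.

These are the quantities used to compare the dynamic condition against the
accept-all control: mean coverage depth over time, the fraction of sites
below a depth threshold, the number of sites whose genotype posterior has not
yet exceeded the resolution threshold, a scale-invariant coverage-evenness
score, the accepted-site fraction of the current strategy, and read-count
abundance estimates (read counts, unlike base yield, remain unbiased under
adaptive sampling).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from poreselect.genotype import ObservationModel, posterior_field
from poreselect.strategy import DecisionStrategy


def low_coverage_fraction(depth: np.ndarray, k: int = 5) -> float:
    """Fraction of sites with depth strictly below k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    depth = np.asarray(depth)
    return float((depth < k).mean())


def max_posterior(
    counts: np.ndarray, log_prior: np.ndarray, model: ObservationModel
) -> np.ndarray:
    """Per-site maximum genotype posterior probability."""
    probs, _ = posterior_field(counts, log_prior, model)
    return probs.max(axis=1)


def unresolved_sites(max_post: np.ndarray, threshold: float = 0.99) -> int:
    """Number of sites whose top genotype probability does not exceed the
    threshold (a site is resolved only when its maximum is strictly greater)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return int((np.asarray(max_post) <= threshold).sum())


def evenness_score(depth: np.ndarray) -> float:
    """Coverage evenness E = (1/N) * sum_i min(depth_i, mean) / mean.

    E = 1 iff coverage is perfectly uniform; invariant under scaling all
    depths by a common factor. Undefined (nan) at zero mean depth.
    """
    depth = np.asarray(depth, dtype=float)
    mean = depth.mean()
    if mean <= 0:
        return float("nan")
    return float(np.minimum(depth, mean).sum() / (len(depth) * mean))


def accepted_fraction(strategy: DecisionStrategy, species: str) -> float:
    """|S| / 2N for one species: fraction of accepted (position, orientation) pairs."""
    return strategy.accepted_fraction(species)


def abundance_estimates(read_log: pd.DataFrame) -> pd.DataFrame:
    """Read-count abundance estimates per condition.

    Counts identified reads (not bases) per species, normalized within each
    condition; robust to the coverage skew that adaptive sampling introduces.
    """
    if len(read_log) == 0:
        raise ValueError("empty read log")
    ident = read_log[read_log["identified"]]
    est = (
        ident.groupby(["condition", "species"]).size().rename("reads").reset_index()
    )
    est["fraction"] = est.groupby("condition")["reads"].transform(
        lambda s: s / s.sum()
    )
    return est


def snapshot_row(
    condition: str,
    time: float,
    species: str,
    depth: np.ndarray,
    counts: np.ndarray,
    log_prior: np.ndarray,
    model: ObservationModel,
    strategy: DecisionStrategy | None,
    low_k: int = 5,
    resolve_threshold: float = 0.99,
) -> dict:
    """One snapshot record of the run-summary time series."""
    mp = max_posterior(counts, log_prior, model)
    return dict(
        condition=condition,
        time=time,
        species=species,
        mean_coverage=float(np.asarray(depth).mean()),
        low_coverage_fraction=low_coverage_fraction(depth, low_k),
        unresolved=unresolved_sites(mp, resolve_threshold),
        evenness=evenness_score(depth),
        accepted_fraction=(
            strategy.accepted_fraction(species) if strategy is not None else 1.0
        ),
    )


def call_variants(
    counts: np.ndarray,
    log_prior: np.ndarray,
    model: ObservationModel,
    ref_codes: np.ndarray,
) -> pd.DataFrame:
    """Posterior-based variant calls: sites whose maximum-posterior genotype
    differs from the reference genotype.

    A deliberately simple internal caller for scoring simulations against the
    planted truth table; not a substitute for a production variant-calling
    pipeline.
    """
    probs, _ = posterior_field(counts, log_prior, model)
    called = probs.argmax(axis=1)
    ref_gt = np.array(
        [model.space.homozygous_index(c) for c in range(4)]
    )[ref_codes]
    alt_sites = np.nonzero(called != ref_gt)[0]
    return pd.DataFrame(
        {
            "pos": alt_sites,
            "genotype": [model.space.label(g) for g in called[alt_sites]],
            "max_posterior": probs[alt_sites].max(axis=1),
        }
    )


def score_calls(called_pos, truth_pos) -> dict:
    """Sensitivity and precision of called variant positions vs planted truth."""
    called = set(int(p) for p in called_pos)
    truth = set(int(p) for p in truth_pos)
    tp = len(called & truth)
    sens = tp / len(truth) if truth else float("nan")
    prec = tp / len(called) if called else float("nan")
    return dict(tp=tp, called=len(called), truth=len(truth),
                sensitivity=sens, precision=prec)


def run_report_tables(result) -> dict:
    """Assemble the report tables of a finished run (deterministic re-derivation
    from the run artifacts)."""
    tables = {"snapshots": result.snapshots, "strategy_history": result.strategy_history}
    tables["abundance"] = abundance_estimates(result.read_log)
    return tables


def plot_run(result, outdir) -> list:
    """Render the standard plot set for a run directory; returns saved paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    snaps = result.snapshots
    panels = [
        ("mean_coverage", "Mean coverage depth"),
        ("low_coverage_fraction", "Fraction of sites < 5x"),
        ("unresolved", "Unresolved sites (max posterior <= 0.99)"),
        ("evenness", "Coverage evenness"),
    ]
    if len(snaps):
        for col, title in panels:
            fig, ax = plt.subplots(figsize=(6, 4))
            for (cond, species), grp in snaps.groupby(["condition", "species"]):
                style = "-" if cond == "dynamic" else "--"
                ax.plot(grp["time"], grp[col], style, label=f"{species} ({cond})")
            ax.set_xlabel("time (base-translocation units)")
            ax.set_ylabel(title)
            ax.legend(fontsize=7)
            fig.tight_layout()
            path = outdir / f"{col}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            paths.append(path)
    if len(result.read_log):
        fig, ax = plt.subplots(figsize=(6, 4))
        for cond, grp in result.read_log.groupby("condition"):
            ax.hist(grp["obs_length"], bins=50, alpha=0.5, label=cond)
        ax.set_xlabel("observed read length (bases)")
        ax.set_ylabel("reads")
        ax.legend()
        fig.tight_layout()
        path = outdir / "read_lengths.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
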