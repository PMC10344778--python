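"""Mock-community generator and closed-loop sequencing-process simulator.

The simulator emulates a flowcell split into a *dynamic* group (decisions made
by the adaptive engine) and a *control* group (accepts everything), sharing
one simulated time budget. Time is counted in base-translocation units: a new
read costs ``alpha`` to acquire; an accepted fragment of length l then costs
l; a rejected fragment costs ``min(l, mu) + rho`` (the decision prefix plus
the rejection overhead). Fragments shorter than mu are always read fully.

Pairing: each group consumes an identically seeded copy of the fragment
stream, so the k-th fragment (origin, orientation, length, haplotype and
identifiability) is the same in both groups regardless of decisions; within a
group, channels share the stream via min-clock scheduling. With an accept-all
strategy and no unidentifiable fragments the two groups produce identical
read logs.

The sample genomes differ from the references by planted SNPs and deletions
(recorded in a truth table that round-trips to VCF), by a smooth positive
coverage-bias field, and by base-call errors at the observation-model rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from poreselect import metrics as _metrics
from poreselect.benefit import score_field
from poreselect.genotype import (
    BASES,
    SYMBOLS,
    GenotypeSpace,
    build_observation_matrix,
    prior_row_for_base,
)
from poreselect.read_model import (
    FORWARD,
    REVERSE,
    ReadLengthDist,
    ReadStartDist,
    TimeModel,
    expected_benefit,
    mu_benefit,
    update_length_dist,
    update_start_dist,
)
from poreselect.runio import RunConfig, seq_to_codes
from poreselect.strategy import DecisionStrategy, compute_strategy, coverage_gate, decide

DEL_CODE = 4


@dataclass
class SpeciesTruth:
    """One community member: reference, true sample genome, abundance, bias."""

    name: str
    ref_codes: np.ndarray        # uint8 codes 0..3
    sample_codes: np.ndarray     # uint8 codes 0..4 (4 = deleted in the sample)
    het_alts: dict               # position -> alt code (heterozygous SNPs)
    abundance: float
    bias: np.ndarray             # positive, mean 1
    bias_cdf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        cdf = np.cumsum(self.bias)
        self.bias_cdf = cdf / cdf[-1]

    @property
    def length(self) -> int:
        return len(self.ref_codes)


@dataclass
class Community:
    """Mock community: species, normalized abundances and the variant truth table."""

    species: list
    truth: pd.DataFrame          # columns: species, pos, ref, alt, zygosity, type

    @property
    def contig_lengths(self) -> dict:
        return {s.name: s.length for s in self.species}

    @property
    def species_probs(self) -> np.ndarray:
        """Fragment-origin probability per species: abundance x length x mean bias."""
        p = np.array([s.abundance * s.length * s.bias.mean() for s in self.species])
        return p / p.sum()

    def to_vcf(self) -> str:
        """Truth table as VCF text (positions 1-based; deletions anchored)."""
        lines = [
            "##fileformat=VCFv4.2",
            '##INFO=<ID=TYPE,Number=1,Type=String,Description="Planted variant type">',
            '##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity">',
        ]
        for s in self.species:
            lines.append(f"##contig=<ID={s.name},length={s.length}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        by_species = {s.name: s for s in self.species}
        for row in self.truth.itertuples(index=False):
            sp = by_species[row.species]
            info = f"TYPE={row.type};ZYG={row.zygosity}"
            if row.type == "del":
                if row.pos > 0:
                    anchor = BASES[sp.ref_codes[row.pos - 1]]
                    lines.append(
                        f"{row.species}\t{row.pos}\t.\t{anchor}{row.ref}\t{anchor}\t.\tPASS\t{info}"
                    )
                else:
                    lines.append(f"{row.species}\t1\t.\t{row.ref}\t<DEL>\t.\tPASS\t{info}")
            else:
                lines.append(
                    f"{row.species}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}"
                )
        return "\n".join(lines) + "\n"

    def sample_fasta(self) -> str:
        """True sample genomes as FASTA (deleted positions omitted)."""
        chunks = []
        for s in self.species:
            seq = "".join(SYMBOLS[c] for c in s.sample_codes if c != DEL_CODE)
            chunks.append(f">{s.name}\n{seq}\n")
        return "".join(chunks)


def coverage_bias_field(n: int, sd: float, scale: int, rng) -> np.ndarray:
    """Smooth positive bias: exponentiated smoothed Gaussian noise, mean 1."""
    if sd <= 0:
        return np.ones(n)
    noise = rng.standard_normal(n)
    z = gaussian_filter1d(noise, sigma=scale, mode="wrap")
    z = z - z.mean()
    std = z.std()
    if std < 1e-12:  # smoothing scale >> genome length: effectively flat
        return np.ones(n)
    bias = np.exp(sd * (z / std))
    return bias / bias.mean()


def random_references(
    n_species: int, length: int, seed: int, gc: float = 0.5
) -> dict:
    """Random reference contigs (synthetic; for simulation-only runs)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"species{i + 1}": "".join(
            np.array(list("ACGT"))[rng.choice(4, size=length, p=p)]
        )
        for i in range(n_species)
    }


def make_community(
    references: dict,
    abundances,
    snp_rate: float = 0.0,
    deletion_rate: float = 0.0,
    het_fraction: float = 0.0,
    seed: int = 0,
    bias_sd: float = 0.3,
    bias_scale: int = 5000,
) -> Community:
    """Plant variants into reference genomes and assemble a mock community.

    SNPs and deletions are planted site-wise at the given per-base rates;
    ``het_fraction`` of planted SNPs are heterozygous (meaningful for diploid
    models; reads then carry the alternate allele on one of two haplotypes).
    Every planted variant is recorded in the truth table. Reproducible by
    seed.
    """
    abundances = np.asarray(abundances, dtype=float)
    if len(abundances) != len(references):
        raise ValueError("abundances must match the number of references")
    if np.any(abundances < 0) or abundances.sum() <= 0:
        raise ValueError("abundances must be non-negative with positive total")
    for name, rate in (("snp_rate", snp_rate), ("deletion_rate", deletion_rate)):
        if not 0 <= rate <= 0.2:
            raise ValueError(f"{name} must be in [0, 0.2], got {rate}")
    abundances = abundances / abundances.sum()

    rng = np.random.default_rng(seed)
    species = []
    rows = []
    for (name, seq), ab in zip(references.items(), abundances):
        ref = seq_to_codes(seq)
        unknown = ref == 255
        if unknown.any():
            ref = ref.copy()
            ref[unknown] = rng.integers(0, 4, size=int(unknown.sum()))
        n = len(ref)
        sample = ref.copy()
        het_alts = {}
        u = rng.random(n)
        snp_pos = np.nonzero(u < snp_rate)[0]
        del_pos = np.nonzero((u >= snp_rate) & (u < snp_rate + deletion_rate))[0]
        if snp_pos.size:
            alts = (ref[snp_pos] + rng.integers(1, 4, size=snp_pos.size)) % 4
            het = rng.random(snp_pos.size) < het_fraction
            for pos, alt, h in zip(snp_pos.tolist(), alts.tolist(), het.tolist()):
                if h:
                    het_alts[pos] = alt
                else:
                    sample[pos] = alt
                rows.append(
                    dict(species=name, pos=pos, ref=BASES[ref[pos]],
                         alt=BASES[alt], zygosity="het" if h else "hom", type="snp")
                )
        if del_pos.size:
            sample[del_pos] = DEL_CODE
            for pos in del_pos.tolist():
                rows.append(
                    dict(species=name, pos=pos, ref=BASES[ref[pos]],
                         alt="-", zygosity="hom", type="del")
                )
        bias = coverage_bias_field(n, bias_sd, bias_scale, rng)
        species.append(
            SpeciesTruth(
                name=name, ref_codes=ref, sample_codes=sample,
                het_alts=het_alts, abundance=float(ab), bias=bias,
            )
        )
    truth = pd.DataFrame(
        rows, columns=["species", "pos", "ref", "alt", "zygosity", "type"]
    ).sort_values(["species", "pos"]).reset_index(drop=True)
    return Community(species=species, truth=truth)


@dataclass(frozen=True)
class FragmentModel:
    """Fragment generation: lognormal lengths, bias-weighted origins, and the
    probability that an initial fragment cannot be identified."""

    mean_length: float = 3110.0
    sigma_log: float = 0.6
    min_length: int = 361
    max_length: int = 20000
    p_unid: float = 0.15

    @property
    def log_mu(self) -> float:
        return float(np.log(self.mean_length) - self.sigma_log**2 / 2.0)


@dataclass(frozen=True)
class Fragment:
    species: int                 # index into community.species
    start: int                   # reference coordinate of the read start
    orientation: int             # 0 forward, 1 reverse
    length: int
    haplotype: int               # 0 or 1 (which chromosome carries het alts)
    unidentifiable: bool

    def ref_interval(self) -> tuple[int, int]:
        if self.orientation == FORWARD:
            return self.start, self.start + self.length
        return self.start - self.length + 1, self.start + 1


def draw_fragment(community: Community, fm: FragmentModel, rng) -> Fragment:
    """Draw one fragment: species by abundance x length x mean bias, start by
    the within-genome bias field, fair-coin orientation, lognormal length
    truncated to fit the genome."""
    probs = community.species_probs
    si = int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))
    si = min(si, len(probs) - 1)
    sp = community.species[si]
    start = int(np.searchsorted(sp.bias_cdf, rng.random(), side="right"))
    start = min(start, sp.length - 1)
    orient = FORWARD if rng.random() < 0.5 else REVERSE
    raw = rng.lognormal(mean=fm.log_mu, sigma=fm.sigma_log)
    length = int(np.clip(raw, fm.min_length, fm.max_length))
    if orient == FORWARD:
        length = min(length, sp.length - start)
    else:
        length = min(length, start + 1)
    length = max(length, 1)
    return Fragment(
        species=si, start=start, orientation=orient, length=length,
        haplotype=int(rng.random() < 0.5),
        unidentifiable=bool(rng.random() < fm.p_unid),
    )


@dataclass
class ChannelState:
    """One simulated pore: clock in base-translocation units and read tally."""

    channel_id: int
    condition: str               # 'dynamic' or 'control'
    clock: float = 0.0
    n_reads: int = 0


def emit_read(
    fragment: Fragment,
    obs_length: int,
    community: Community,
    phi_hap: np.ndarray,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Base-call the observed part of a fragment.

    Returns (reference positions, observed symbol codes), reference-oriented.
    Each site's observed symbol is drawn from the haploid observation row of
    its true allele (planted het SNPs follow the fragment's haplotype), so an
    error-free model reproduces the sample genome exactly.
    """
    sp = community.species[fragment.species]
    if fragment.orientation == FORWARD:
        lo, hi = fragment.start, fragment.start + obs_length
    else:
        lo, hi = fragment.start - obs_length + 1, fragment.start + 1
    positions = np.arange(lo, hi)
    true = sp.sample_codes[lo:hi].astype(np.int64)
    if fragment.haplotype == 1 and sp.het_alts:
        for pos, alt in sp.het_alts.items():
            if lo <= pos < hi:
                true[pos - lo] = alt
    cum = np.cumsum(phi_hap, axis=1)
    u = rng.random(len(true))
    obs = (u[:, None] < cum[true]).argmax(axis=1)
    return positions, obs.astype(np.int64)


def sequence_step(
    channel: ChannelState,
    fragment: Fragment,
    strategy: DecisionStrategy | None,
    time: TimeModel,
    community: Community,
    phi_hap: np.ndarray,
    rng,
) -> dict:
    """Process one fragment on one pore and advance its clock.

    ``strategy=None`` denotes the control condition (everything accepted).
    Rejection costs alpha + min(l, mu) + rho and observes min(l, mu) bases;
    acceptance costs alpha + l. Fragments no longer than mu are read fully
    and never rejected. Unidentifiable fragments are rejected under the
    dynamic condition (a false rejection when their origin was accepted).
    """
    sp = community.species[fragment.species]
    l = fragment.length
    if strategy is None:
        accepted = True
        identified = True
    elif l <= time.mu:
        accepted = True
        identified = not fragment.unidentifiable
    elif fragment.unidentifiable:
        accepted = False
        identified = False
    else:
        accepted = decide((sp.name, fragment.start, fragment.orientation), strategy)
        identified = True
    if accepted:
        obs_length = l
        cost = time.alpha + l
    else:
        obs_length = min(l, time.mu)
        cost = time.alpha + obs_length + time.rho
    channel.clock += cost
    channel.n_reads += 1
    positions, obs = emit_read(fragment, obs_length, community, phi_hap, rng)
    return dict(
        condition=channel.condition,
        channel=channel.channel_id,
        species=sp.name,
        start=fragment.start,
        orientation=fragment.orientation,
        true_length=l,
        obs_length=obs_length,
        accepted=accepted,
        identified=identified,
        cost=cost,
        clock=channel.clock,
        _positions=positions,
        _obs=obs,
    )


@dataclass
class RunResult:
    """Artifacts of one paired simulation run."""

    config: RunConfig
    community: Community
    read_log: pd.DataFrame
    counts: dict                 # condition -> species -> (N, 5) counts
    depth: dict                  # condition -> species -> (N,) coverage depth
    strategy_history: pd.DataFrame
    snapshots: pd.DataFrame
    final_strategy: DecisionStrategy
    length_dist: ReadLengthDist
    start_dist: ReadStartDist


def _recompute_strategy(
    community, counts, depth, log_priors, model, length_dist, start_dist,
    time, cfg, allowed, step, scores=None, dirty=None,
):
    u, smu = {}, {}
    for sp in community.species:
        if scores is None:
            s = score_field(counts[sp.name], log_priors[sp.name], model)
        else:
            # incremental: rescore only sites whose counts changed
            s = scores[sp.name]
            idx = np.nonzero(dirty[sp.name])[0]
            if idx.size:
                s[idx] = score_field(
                    counts[sp.name][idx], log_priors[sp.name][idx], model
                )
                dirty[sp.name][idx] = False
        u[sp.name] = np.stack([
            expected_benefit(s, length_dist, FORWARD),
            expected_benefit(s, length_dist, REVERSE),
        ])
        smu[sp.name] = np.stack([
            mu_benefit(s, time.mu, FORWARD),
            mu_benefit(s, time.mu, REVERSE),
        ])
    w = start_dist.probs()
    forced = coverage_gate(depth, cfg.gate_window, cfg.gate_min_coverage)
    lam = length_dist.mean
    return compute_strategy(
        u, smu, w, time, lam, allowed=allowed, forced=forced, step=step
    )


def run_experiment(
    config: RunConfig,
    community: Community | None = None,
    rois: dict | None = None,
) -> RunResult:
    """Run the paired dynamic-vs-control closed-loop simulation.

    Both condition groups receive identically seeded fragment streams and
    equal per-channel time budgets; the dynamic group periodically recomputes
    benefit fields and the decision strategy from its accumulated counts
    (coverage-gated per 20-kb window), while the control group accepts every
    fragment. All randomness derives from ``config.seed``; results are
    reproducible bit for bit.
    """
    from poreselect.runio import read_fasta
    from poreselect.strategy import apply_roi_mask

    if community is None:
        if not config.reference_paths:
            raise ValueError("run_experiment needs a community or reference_paths")
        refs = {}
        for path in config.reference_paths:
            for name, seq in read_fasta(path).items():
                if name in refs:
                    raise ValueError(f"duplicate contig name {name!r} across references")
                refs[name] = seq
        community = make_community(
            refs,
            config.abundances or [1.0] * len(refs),
            snp_rate=config.snp_rate,
            deletion_rate=config.deletion_rate,
            het_fraction=config.het_fraction,
            seed=config.seed,
            bias_sd=config.bias_sd,
            bias_scale=config.bias_scale,
        )

    time = TimeModel(alpha=config.alpha, rho=config.rho, mu=config.mu)
    model = build_observation_matrix(
        config.error_rate,
        (config.spurious_deletion, config.deletion_miscall),
        ploidy=config.ploidy,
    )
    phi_hap = build_observation_matrix(
        config.error_rate, (config.spurious_deletion, config.deletion_miscall), ploidy=1
    ).phi
    space = GenotypeSpace(ploidy=config.ploidy, include_deletion=True)
    log_priors = {}
    ref_codes = {}
    for sp in community.species:
        rows = np.stack([
            prior_row_for_base(c, space, config.prior_weight) for c in range(4)
        ])
        with np.errstate(divide="ignore"):
            log_rows = np.log(rows)
        log_priors[sp.name] = log_rows[sp.ref_codes]
        ref_codes[sp.name] = sp.ref_codes

    contig_lengths = community.contig_lengths
    allowed = apply_roi_mask(contig_lengths, rois, config.roi_flank) if rois else None
    fm = FragmentModel(
        mean_length=config.mean_fragment_length,
        sigma_log=config.fragment_sigma_log,
        min_length=min(config.mu + 1, config.max_read_length),
        max_length=config.max_read_length,
        p_unid=config.p_unid,
    )

    grid = np.linspace(0, config.time_budget, config.n_snapshots + 1)[1:]
    log_rows_out = []
    history_rows = []
    snapshot_rows = []
    counts_by_cond = {}
    depth_by_cond = {}
    final_strategy = DecisionStrategy.accept_all(contig_lengths, step=0)
    final_length_dist = None
    final_start_dist = None

    ss = np.random.SeedSequence(config.seed)
    frag_seed, noise_seed = ss.spawn(2)

    for condition in ("dynamic", "control"):
        # identically seeded per group: the fragment stream is paired
        rng_frag = np.random.default_rng(frag_seed)
        rng_noise = np.random.default_rng(noise_seed)
        channels = [ChannelState(i, condition) for i in range(config.n_channels)]
        counts = {sp.name: np.zeros((sp.length, 5), dtype=np.int64)
                  for sp in community.species}
        depth = {sp.name: np.zeros(sp.length, dtype=np.int64)
                 for sp in community.species}
        dynamic = condition == "dynamic"
        strategy = DecisionStrategy.accept_all(contig_lengths, step=0)
        # per-site score cache: rescore only sites touched since last update
        scores = {
            sp.name: score_field(counts[sp.name], log_priors[sp.name], model)
            for sp in community.species
        } if dynamic else None
        dirty = {sp.name: np.zeros(sp.length, dtype=bool)
                 for sp in community.species} if dynamic else None
        length_dist = ReadLengthDist.from_truncated_normal(
            mean=config.length_prior_mean, sd=config.length_prior_sd,
            lower=config.mu, max_length=config.max_read_length,
            prior_weight=config.length_prior_weight,
        )
        start_dist = ReadStartDist(contig_lengths=dict(contig_lengths))
        if dynamic:
            history_rows.append(
                dict(step=0, time=0.0, reads=0, ratio=strategy.ratio,
                     **{f"accepted_{sp.name}": 1.0 for sp in community.species})
            )
        pending_lengths = []
        pending_starts = []
        mapped_since_update = 0
        n_updates = 0
        grid_idx = 0
        last_update_time = 0.0
        interval_units = config.update_interval_seconds * config.translocation_speed

        while True:
            channel = min(channels, key=lambda c: (c.clock, c.channel_id))
            if channel.clock >= config.time_budget:
                break
            fragment = draw_fragment(community, fm, rng_frag)
            read = sequence_step(
                channel, fragment,
                strategy if dynamic else None,
                time, community, phi_hap, rng_noise,
            )
            positions = read.pop("_positions")
            obs = read.pop("_obs")
            if read["identified"]:
                sp_name = read["species"]
                np.add.at(counts[sp_name], (positions, obs), 1)
                depth[sp_name][positions[0]: positions[-1] + 1] += 1
                if dynamic:
                    dirty[sp_name][positions[0]: positions[-1] + 1] = True
                pending_starts.append((sp_name, read["start"], read["orientation"]))
                if read["accepted"]:
                    pending_lengths.append(read["true_length"])
                mapped_since_update += 1
            log_rows_out.append(read)

            group_time = min(c.clock for c in channels)
            # update cadence: every update_interval_seconds of simulated time
            # or update_reads newly mapped reads, whichever comes first
            due = mapped_since_update >= config.update_reads or (
                mapped_since_update > 0
                and interval_units > 0
                and group_time - last_update_time >= interval_units
            )
            if dynamic and due:
                length_dist = update_length_dist(length_dist, pending_lengths)
                start_dist = update_start_dist(start_dist, pending_starts)
                pending_lengths, pending_starts = [], []
                mapped_since_update = 0
                last_update_time = group_time
                n_updates += 1
                strategy = _recompute_strategy(
                    community, counts, depth, log_priors, model,
                    length_dist, start_dist, time, config, allowed, n_updates,
                    scores=scores, dirty=dirty,
                )
                history_rows.append(
                    dict(step=n_updates, time=group_time,
                         reads=sum(c.n_reads for c in channels),
                         ratio=strategy.ratio,
                         **{f"accepted_{sp.name}":
                            strategy.accepted_fraction(sp.name)
                            for sp in community.species})
                )

            group_time = min(c.clock for c in channels)
            while grid_idx < len(grid) and group_time >= grid[grid_idx]:
                for sp in community.species:
                    snapshot_rows.append(
                        _metrics.snapshot_row(
                            condition, float(grid[grid_idx]), sp.name,
                            depth[sp.name], counts[sp.name],
                            log_priors[sp.name], model,
                            strategy if dynamic else None,
                        )
                    )
                grid_idx += 1

        counts_by_cond[condition] = counts
        depth_by_cond[condition] = depth
        if dynamic:
            final_strategy = strategy
            final_length_dist = length_dist
            final_start_dist = start_dist

    read_log = pd.DataFrame(
        log_rows_out,
        columns=["condition", "channel", "species", "start", "orientation",
                 "true_length", "obs_length", "accepted", "identified",
                 "cost", "clock"],
    )
    return RunResult(
        config=config,
        community=community,
        read_log=read_log,
        counts=counts_by_cond,
        depth=depth_by_cond,
        strategy_history=pd.DataFrame(history_rows),
        snapshots=pd.DataFrame(snapshot_rows),
        final_strategy=final_strategy,
        length_dist=final_length_dist,
        start_dist=final_start_dist,
    )
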