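"""Per-site genotype probability model.

At every reference position we maintain a probability distribution over
genotypes. The prior is informed by the reference base; the posterior is
updated with the bases observed in reads covering the site, through an
observation (error) matrix that accounts for ploidy, substitution errors and
(optionally) a deletion allele. Counts of observed symbols are sufficient
statistics, so the posterior is

    f(g | D) = pi(g) * prod_d phi(d | g)^count(d) / Z(D),

computed in log space, with Z(D) the data likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

# Canonical symbol order, stable across all modules.
BASES = ("A", "C", "G", "T")
DEL = "-"
SYMBOLS = BASES + (DEL,)

BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
SYMBOL_TO_CODE = {s: i for i, s in enumerate(SYMBOLS)}


class ParameterError(ValueError):
    """A model constant lies outside its valid domain."""


class DegeneratePosteriorError(ValueError):
    """All genotype mass was annihilated by zero-probability entries."""


@dataclass(frozen=True)
class GenotypeSpace:
    """Ordered genotype set for a given ploidy over the (extended) alphabet.

    Haploid genotypes are single alleles; diploid genotypes are unordered
    allele pairs (combinations with repetition), giving k(k+1)/2 genotypes
    for k alleles. Ordering is canonical: alleles in alphabet order, pairs in
    lexicographic order of their sorted allele indices.
    """

    ploidy: int
    include_deletion: bool

    def __post_init__(self):
        if self.ploidy not in (1, 2):
            raise ParameterError(f"ploidy must be 1 or 2, got {self.ploidy}")

    @property
    def alleles(self) -> tuple[str, ...]:
        return SYMBOLS if self.include_deletion else BASES

    @property
    def n_symbols(self) -> int:
        """Number of observable symbols (columns of phi)."""
        return len(self.alleles)

    @property
    def genotypes(self) -> tuple[tuple[int, ...], ...]:
        k = len(self.alleles)
        if self.ploidy == 1:
            return tuple((i,) for i in range(k))
        return tuple(combinations_with_replacement(range(k), 2))

    def __len__(self) -> int:
        return len(self.genotypes)

    def label(self, idx: int) -> str:
        return "/".join(self.alleles[a] for a in self.genotypes[idx])

    def index_of(self, alleles: tuple[int, ...]) -> int:
        return self.genotypes.index(tuple(sorted(alleles)))

    def homozygous_index(self, allele: int) -> int:
        return self.index_of((allele,) * self.ploidy)


@dataclass(frozen=True)
class ObservationModel:
    """phi(d | g): probability of calling symbol d given true genotype g.

    Rows index genotypes, columns observed symbols; each row sums to 1.
    Diploid rows are the equal-weight mixture of the two constituent haploid
    rows (each read samples one of the two chromosomes uniformly).
    """

    space: GenotypeSpace
    phi: np.ndarray           # (n_genotypes, n_symbols)
    error_rate: float
    spurious_deletion: float
    deletion_miscall: float
    log_phi: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        with np.errstate(divide="ignore"):
            object.__setattr__(self, "log_phi", np.log(self.phi))


def build_observation_matrix(
    error_rate: float,
    deletion_params: tuple[float, float] | None = (0.05, 0.1),
    ploidy: int = 1,
) -> ObservationModel:
    """Build the observation matrix phi for the given error model and ploidy.

    Parameters
    ----------
    error_rate
        Substitution error probability epsilon; a miscalled base is one of the
        three other bases with equal probability epsilon/3.
    deletion_params
        ``(spurious_deletion, deletion_miscall)``: the probability delta_s of
        calling a deletion over a non-deleted allele, and the probability
        delta_m of calling any base over a deleted allele (spread equally over
        the four bases). ``None`` disables the deletion allele entirely
        (SNP-only 4x4 model).
    ploidy
        1 or 2.
    """
    if not 0 <= error_rate < 1:
        raise ParameterError(f"error_rate must be in [0, 1), got {error_rate}")
    include_del = deletion_params is not None
    if include_del:
        ds, dm = deletion_params
        if not (0 <= ds < 1 and 0 <= dm < 1):
            raise ParameterError(f"deletion params must be in [0, 1), got {deletion_params}")
    else:
        ds = dm = 0.0

    space = GenotypeSpace(ploidy=ploidy, include_deletion=include_del)
    k = space.n_symbols

    # Haploid rows first; diploid rows are mixtures of them.
    n_hap = k
    hap = np.zeros((n_hap, k))
    for g in range(4):
        snp = np.full(4, error_rate / 3.0)
        snp[g] = 1.0 - error_rate
        if include_del:
            hap[g, :4] = (1.0 - ds) * snp
            hap[g, 4] = ds
        else:
            hap[g, :4] = snp
    if include_del:
        hap[4, :4] = dm / 4.0
        hap[4, 4] = 1.0 - dm

    if ploidy == 1:
        phi = hap
    else:
        phi = np.array([(hap[a] + hap[b]) / 2.0 for a, b in space.genotypes])

    return ObservationModel(
        space=space, phi=phi, error_rate=error_rate,
        spurious_deletion=ds, deletion_miscall=dm,
    )


@dataclass(frozen=True)
class GenotypePrior:
    """Per-site prior probability vectors pi_i(g), shape (n_sites, n_genotypes).

    Rows are entirely determined by the reference base at the site (uniform at
    ambiguity codes), so at most six distinct rows occur.
    """

    space: GenotypeSpace
    matrix: np.ndarray
    prior_weight: float

    def row(self, i: int) -> np.ndarray:
        return self.matrix[i]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]


def prior_row_for_base(
    ref_code: int | None, space: GenotypeSpace, prior_weight: float
) -> np.ndarray:
    """Prior vector for a site with the given reference base code.

    The genotype matching the reference (haploid: the ref allele; diploid:
    homozygous ref) receives ``prior_weight``. Remaining mass: haploid, split
    equally over the other alleles; diploid, split 2:1 between heterozygotes
    containing the reference allele (equally among them) and all remaining
    genotypes (equally). ``ref_code=None`` (ambiguity code) yields a uniform
    prior: no information should mean no bias.
    """
    n_g = len(space)
    if ref_code is None:
        return np.full(n_g, 1.0 / n_g)
    row = np.zeros(n_g)
    rest = 1.0 - prior_weight
    if space.ploidy == 1:
        row[:] = rest / (n_g - 1) if n_g > 1 else 0.0
        row[space.index_of((ref_code,))] = prior_weight
    else:
        het_idx = [
            j for j, g in enumerate(space.genotypes)
            if ref_code in g and g[0] != g[1]
        ]
        hom_idx = space.homozygous_index(ref_code)
        other_idx = [
            j for j in range(n_g) if j != hom_idx and j not in het_idx
        ]
        for j in het_idx:
            row[j] = rest * (2.0 / 3.0) / len(het_idx)
        for j in other_idx:
            row[j] = rest * (1.0 / 3.0) / len(other_idx)
        row[hom_idx] = prior_weight
    return row


def build_priors(
    reference_sequence: str,
    prior_weight: float = 0.99,
    ploidy: int = 1,
    include_deletion: bool = True,
) -> GenotypePrior:
    """Reference-informed per-site genotype priors for one contig."""
    if not 0 < prior_weight <= 1:
        raise ParameterError(f"prior_weight must be in (0, 1], got {prior_weight}")
    if len(reference_sequence) == 0:
        raise ValueError("empty reference sequence")
    space = GenotypeSpace(ploidy=ploidy, include_deletion=include_deletion)
    rows = {
        code: prior_row_for_base(code, space, prior_weight)
        for code in range(4)
    }
    uniform = prior_row_for_base(None, space, prior_weight)
    n_unknown = 0
    matrix = np.empty((len(reference_sequence), len(space)))
    for i, ch in enumerate(reference_sequence.upper()):
        code = BASE_TO_CODE.get(ch)
        if code is None:
            matrix[i] = uniform
            n_unknown += 1
        else:
            matrix[i] = rows[code]
    if n_unknown:
        logger.info(
            "build_priors: %d site(s) with non-ACGT reference symbols "
            "received a uniform prior", n_unknown,
        )
    return GenotypePrior(space=space, matrix=matrix, prior_weight=prior_weight)


@dataclass(frozen=True)
class PosteriorDist:
    """Normalized genotype posterior at one site, with data likelihood Z."""

    probs: np.ndarray
    z: float

    @property
    def max_prob(self) -> float:
        return float(self.probs.max())

    def argmax(self) -> int:
        # ties broken by canonical genotype order (np.argmax takes the first)
        return int(np.argmax(self.probs))


def posterior(
    counts: np.ndarray, prior: np.ndarray, model: ObservationModel
) -> PosteriorDist:
    """Genotype posterior at one site from observed symbol counts.

    ``counts`` is an integer vector over observed symbols (canonical order);
    ``prior`` a probability vector over the model's genotype space. Returns
    the normalized posterior and the likelihood Z. With zero counts the
    posterior equals the prior and Z = 1.
    """
    counts = np.asarray(counts)
    if counts.shape != (model.space.n_symbols,):
        raise ValueError(
            f"counts must have shape ({model.space.n_symbols},), got {counts.shape}"
        )
    if np.any(counts < 0):
        raise ValueError("negative counts")
    with np.errstate(divide="ignore"):
        log_prior = np.log(np.asarray(prior, dtype=float))
    # sum only over observed symbols: avoids 0 * (-inf) = nan when phi has
    # exact zeros (error-free limit)
    (nz,) = np.nonzero(counts)
    log_lik = model.log_phi[:, nz] @ counts[nz] if nz.size else 0.0
    log_unnorm = log_prior + log_lik
    log_z = logsumexp(log_unnorm)
    if not np.isfinite(log_z):
        raise DegeneratePosteriorError(
            "posterior has zero total mass (zero-probability prior entries "
            "annihilated the likelihood)"
        )
    probs = np.exp(log_unnorm - log_z)
    probs /= probs.sum()
    return PosteriorDist(probs=probs, z=float(np.exp(log_z)))


def posterior_field(
    counts: np.ndarray, log_prior: np.ndarray, model: ObservationModel
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized posteriors for many sites at once.

    Parameters
    ----------
    counts
        (n_sites, n_symbols) integer counts.
    log_prior
        (n_sites, n_genotypes) log prior rows.

    Returns
    -------
    probs : (n_sites, n_genotypes) normalized posteriors
    log_unnorm : (n_sites, n_genotypes) unnormalized log posteriors
        (log prior + log likelihood), useful for incremental updates.
    """
    # clamp -inf to a huge negative finite value so that 0 * log(0) = 0 in
    # the matrix product (exact zeros only occur in degenerate error models)
    log_phi = np.where(np.isneginf(model.log_phi), -1e300, model.log_phi)
    log_unnorm = log_prior + counts @ log_phi.T
    m = log_unnorm.max(axis=1, keepdims=True)
    w = np.exp(log_unnorm - m)
    probs = w / w.sum(axis=1, keepdims=True)
    return probs, log_unnorm
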