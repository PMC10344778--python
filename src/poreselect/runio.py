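"""Readers, writers and the run configuration.

Formats handled: FASTA references (via Biopython), PAF mappings in the
minimap2 dialect (with cs/CIGAR tags for base-level pileup), BED regions of
interest, bedGraph score exports, TOML run configuration, and the per-contig
packed-Boolean strategy files consumed by the sequencer-side controller.

Coordinates are 0-based, half-open everywhere internally. Reverse-strand
reads are indexed by the leftmost reference coordinate of their alignment
together with the reverse-orientation flag.
"""

from __future__ import annotations

import json
import logging
import os
import re
import tempfile
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio import SeqIO

from poreselect.genotype import BASE_TO_CODE, SYMBOL_TO_CODE
from poreselect.read_model import FORWARD, REVERSE, mu_from_chunk
from poreselect.strategy import DecisionStrategy

logger = logging.getLogger(__name__)

DEL_CODE = SYMBOL_TO_CODE["-"]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict:
    """Read a (multi-contig) FASTA into {name: uppercase sequence}.

    Soft-masking is ignored; duplicate contig names and empty files are
    rejected.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return contigs


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3; any other symbol as 255 (unknown)."""
    out = np.full(len(seq), 255, dtype=np.uint8)
    for base, code in BASE_TO_CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return out


@dataclass(frozen=True)
class MappingRecord:
    """One PAF alignment line (target coordinates 0-based, end exclusive)."""

    read_id: str
    read_length: int
    query_start: int
    query_end: int
    strand: str                  # '+' or '-'
    contig: str
    contig_length: int
    target_start: int
    target_end: int
    mapq: int
    align_score: int | None = None
    cs: str | None = None
    cigar: str | None = None

    @property
    def orientation(self) -> int:
        return FORWARD if self.strand == "+" else REVERSE


def parse_paf(source) -> list:
    """Parse PAF records from a path or an iterable of lines."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_paf(fh.readlines())
    records = []
    for lineno, line in enumerate(source, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise ValueError(f"malformed PAF line {lineno}: expected >=12 fields, got {len(parts)}")
        tags = {}
        for tag in parts[12:]:
            try:
                name, typ, value = tag.split(":", 2)
            except ValueError:
                raise ValueError(f"malformed PAF tag {tag!r} on line {lineno}")
            tags[name] = int(value) if typ == "i" else value
        rec = MappingRecord(
            read_id=parts[0],
            read_length=int(parts[1]),
            query_start=int(parts[2]),
            query_end=int(parts[3]),
            strand=parts[4],
            contig=parts[5],
            contig_length=int(parts[6]),
            target_start=int(parts[7]),
            target_end=int(parts[8]),
            mapq=int(parts[11]),
            align_score=tags.get("AS"),
            cs=tags.get("cs"),
            cigar=tags.get("cg"),
        )
        if rec.strand not in "+-":
            raise ValueError(f"invalid strand {rec.strand!r} on PAF line {lineno}")
        if not 0 <= rec.target_start <= rec.target_end <= rec.contig_length:
            raise ValueError(f"target interval out of contig bounds on PAF line {lineno}")
        records.append(rec)
    return records


def select_best_mapping(records) -> MappingRecord | None:
    """Best alignment for one read: highest mapping quality, ties broken by
    alignment score, remaining ties by (contig, position, strand) order.
    Empty input means the read is unmapped."""
    records = list(records)
    if not records:
        return None
    ids = {r.read_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records from multiple reads: {sorted(ids)}")
    return min(
        records,
        key=lambda r: (
            -r.mapq,
            -(r.align_score if r.align_score is not None else -np.inf),
            r.contig,
            r.target_start,
            r.strand,
        ),
    )


_CS_TOKEN = re.compile(r"(:\d+|=[A-Za-z]+|\*[a-z][a-z]|\+[a-z]+|-[a-z]+)")


def _pileup_from_cs(counts: np.ndarray, ref_codes: np.ndarray, start: int, cs: str) -> None:
    pos = start
    consumed = 0
    for m in _CS_TOKEN.finditer(cs):
        tok = m.group(0)
        consumed += len(tok)
        op, val = tok[0], tok[1:]
        if op == ":":
            run = int(val)
            idx = np.arange(pos, pos + run)
            np.add.at(counts, (idx, ref_codes[idx]), 1)
            pos += run
        elif op == "=":
            run = len(val)
            idx = np.arange(pos, pos + run)
            np.add.at(counts, (idx, ref_codes[idx]), 1)
            pos += run
        elif op == "*":
            counts[pos, BASE_TO_CODE[val[1].upper()]] += 1
            pos += 1
        elif op == "-":
            counts[pos: pos + len(val), DEL_CODE] += 1
            pos += len(val)
        # '+' insertion: no reference advance, not modelled
    if consumed != len(cs):
        raise ValueError(f"unparseable cs tag near offset {consumed}: {cs[consumed:consumed+10]!r}")


_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


def _pileup_from_cigar(
    counts: np.ndarray, ref_codes: np.ndarray, rec: MappingRecord, read_bases: str
) -> None:
    if rec.strand == "-":
        seq = revcomp(read_bases)
        q = rec.read_length - rec.query_end
    else:
        seq = read_bases
        q = rec.query_start
    pos = rec.target_start
    for m in _CIGAR_TOKEN.finditer(rec.cigar):
        run, op = int(m.group(1)), m.group(2)
        if op in "M=X":
            idx = np.arange(pos, pos + run)
            codes = seq_to_codes(seq[q: q + run])
            ok = codes != 255
            np.add.at(counts, (idx[ok], codes[ok]), 1)
            pos += run
            q += run
        elif op == "I":
            q += run
        elif op in "DN":
            counts[pos: pos + run, DEL_CODE] += 1
            pos += run
        elif op in "SH":
            q += run if op == "S" else 0


def pileup_update(
    counts: dict,
    record: MappingRecord,
    references: dict,
    read_bases: str | None = None,
) -> None:
    """Increment per-site symbol counts along one alignment.

    ``counts`` maps contig -> (N, 5) integer array over (A, C, G, T, DEL);
    ``references`` maps contig -> reference code array (see
    :func:`seq_to_codes`). Base-level counts come from the cs tag when
    present, else from the CIGAR plus the read sequence; with neither, a
    match is assumed along the mapped span (mismatches unobservable — logged
    as degraded mode). Deleted reference positions receive a DEL count;
    insertions are ignored.
    """
    arr = counts[record.contig]
    ref_codes = references[record.contig]
    if record.target_end > len(ref_codes):
        raise ValueError(
            f"alignment end {record.target_end} beyond contig {record.contig!r} "
            f"length {len(ref_codes)}"
        )
    if record.cs is not None:
        _pileup_from_cs(arr, ref_codes, record.target_start, record.cs)
    elif record.cigar is not None and read_bases is not None:
        _pileup_from_cigar(arr, ref_codes, record, read_bases)
    else:
        logger.warning(
            "pileup_update: no cs/CIGAR detail for read %s; assuming matches "
            "along the mapped span (degraded mode)", record.read_id,
        )
        idx = np.arange(record.target_start, record.target_end)
        np.add.at(arr, (idx, ref_codes[idx]), 1)


# ---------------------------------------------------------------------------
# strategy serialization: one packed-Boolean file per contig

_MAGIC = b"PORESELECT-STRATEGY\t1\n"


class CorruptStrategyError(ValueError):
    """Strategy file failed validation (truncation or header mismatch)."""


def _atomic_write(path: Path, payload: bytes) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=".tmp-strategy-")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)  # a concurrent reader never sees a partial file
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_strategy(directory, strategy: DecisionStrategy) -> dict:
    """Write one packed-Boolean bitmap file per contig; returns {contig: path}.

    Files are written atomically (temp file + rename)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for contig, mask in strategy.masks.items():
        n = mask.shape[1]
        bits = np.packbits(mask.ravel())
        header = json.dumps(
            {"contig": contig, "length": n, "step": strategy.step, "nbytes": len(bits)}
        ).encode() + b"\n"
        path = directory / f"{contig}.strategy"
        _atomic_write(path, _MAGIC + header + bits.tobytes())
        paths[contig] = path
    return paths


def read_strategy(directory) -> DecisionStrategy:
    """Read all per-contig strategy files from a directory."""
    directory = Path(directory)
    files = sorted(directory.glob("*.strategy"))
    if not files:
        raise FileNotFoundError(f"no .strategy files in {directory}")
    masks = {}
    step = 0
    for path in files:
        raw = path.read_bytes()
        if not raw.startswith(_MAGIC):
            raise CorruptStrategyError(f"{path}: bad magic")
        rest = raw[len(_MAGIC):]
        try:
            header_line, payload = rest.split(b"\n", 1)
            header = json.loads(header_line)
        except (ValueError, json.JSONDecodeError) as exc:
            raise CorruptStrategyError(f"{path}: unreadable header") from exc
        n = header["length"]
        expected = header["nbytes"]
        if expected != int(np.ceil(2 * n / 8)) or len(payload) != expected:
            raise CorruptStrategyError(
                f"{path}: payload length {len(payload)} != expected {expected}"
            )
        bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8), count=2 * n)
        masks[header["contig"]] = bits.reshape(2, n).astype(bool)
        step = header["step"]
    return DecisionStrategy(masks=masks, step=step)


def _mask_intervals(row: np.ndarray):
    padded = np.concatenate([[False], row, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return zip(starts.tolist(), ends.tolist())


def strategy_to_bed(strategy: DecisionStrategy) -> str:
    """Human-readable BED export of accepted intervals per orientation."""
    lines = []
    for contig, mask in strategy.masks.items():
        for o, name in ((FORWARD, "accept_forward"), (REVERSE, "accept_reverse")):
            for start, end in _mask_intervals(mask[o]):
                strand = "+" if o == FORWARD else "-"
                lines.append(f"{contig}\t{start}\t{end}\t{name}\t0\t{strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_bed(path) -> dict:
    """Read ROI intervals: {contig: [(start, end), ...]}."""
    rois: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno} in {path}")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"malformed BED interval [{start}, {end}) on line {lineno}")
            rois.setdefault(parts[0], []).append((start, end))
    return rois


def write_bedgraph(path, fields: dict) -> None:
    """Export per-site score arrays ({contig: values}) as bedGraph."""
    with open(path, "w") as fh:
        for contig, values in fields.items():
            values = np.asarray(values)
            # run-length compress equal consecutive values
            change = np.nonzero(np.diff(values))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(values)]])
            for s, e in zip(starts.tolist(), ends.tolist()):
                fh.write(f"{contig}\t{s}\t{e}\t{values[s]:.6g}\n")


# ---------------------------------------------------------------------------
# run configuration

class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated run configuration with derived quantities.

    Time constants are in base-translocation units (one base = one unit;
    450 nt/s by default). ``mu`` is derived from ``chunk_seconds`` x
    ``translocation_speed``.
    """

    # sequencing-process constants
    alpha: float = 300.0
    rho: float = 300.0
    chunk_seconds: float = 0.8
    translocation_speed: float = 450.0
    # observation model
    error_rate: float = 0.03
    spurious_deletion: float = 0.05
    deletion_miscall: float = 0.1
    prior_weight: float = 0.99
    ploidy: int = 1
    # strategy updates
    update_reads: int = 500
    update_interval_seconds: float = 10.0
    gate_window: int = 20000
    gate_min_coverage: float = 5.0
    roi_flank: int = 5000
    # references / community
    reference_paths: list = field(default_factory=list)
    roi_paths: list = field(default_factory=list)
    abundances: list = field(default_factory=list)
    snp_rate: float = 0.0
    deletion_rate: float = 0.0
    het_fraction: float = 0.0
    # fragment / simulator model
    mean_fragment_length: float = 3110.0
    fragment_sigma_log: float = 0.6
    max_read_length: int = 20000
    p_unid: float = 0.15
    bias_sd: float = 0.3
    bias_scale: int = 5000
    # length-distribution prior
    length_prior_mean: float = 3000.0
    length_prior_sd: float = 1500.0
    length_prior_weight: float = 100.0
    # run shape
    n_channels: int = 2
    time_budget: float = 1_250_000.0
    n_snapshots: int = 20
    seed: int = 1

    def __post_init__(self):
        self.validate()

    @property
    def mu(self) -> int:
        return mu_from_chunk(self.chunk_seconds, self.translocation_speed)

    def validate(self) -> None:
        probs = {
            "error_rate": self.error_rate,
            "spurious_deletion": self.spurious_deletion,
            "deletion_miscall": self.deletion_miscall,
            "p_unid": self.p_unid,
            "het_fraction": self.het_fraction,
        }
        for name, value in probs.items():
            if not 0 <= value < 1:
                raise ConfigError(f"{name} must be in [0, 1), got {value}")
        if not 0 < self.prior_weight <= 1:
            raise ConfigError(f"prior_weight must be in (0, 1], got {self.prior_weight}")
        if self.ploidy not in (1, 2):
            raise ConfigError(f"ploidy must be 1 or 2, got {self.ploidy}")
        for name in ("alpha", "rho", "chunk_seconds", "translocation_speed",
                     "time_budget", "mean_fragment_length"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for rate in ("snp_rate", "deletion_rate"):
            if not 0 <= getattr(self, rate) <= 0.2:
                raise ConfigError(f"{rate} must be in [0, 0.2]")
        # abundance count vs contig count is validated when references load
        if self.abundances and any(a < 0 for a in self.abundances):
            raise ConfigError("abundances must be non-negative")
        if self.n_channels < 1 or self.update_reads < 1 or self.n_snapshots < 1:
            raise ConfigError("n_channels, update_reads and n_snapshots must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved(self) -> dict:
        """Config echo including derived quantities, for the run log."""
        out = asdict(self)
        out["mu"] = self.mu
        return out

    def to_toml_str(self) -> str:
        lines = []
        for key, value in self.resolved().items():
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            elif isinstance(value, list):
                items = ", ".join(
                    f'"{v}"' if isinstance(v, str) else repr(v) for v in value
                )
                lines.append(f"{key} = [{items}]")
            else:
                lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"
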