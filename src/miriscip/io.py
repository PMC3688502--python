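"""Readers and writers for every external file the pipeline touches.

Formats are deliberately plain: FASTA for sequences, strict TSV (no
quoting, "." decimal point) for tables, one-identifier-per-line text for
gene sets.  All sequences are normalized to DNA uppercase internally
(U→T), so RNA-alphabet miRNA FASTA files are accepted on input.

Output tables carry a single ``#``-prefixed provenance header line
recording the tool version and the parameters that produced them.
"""

from __future__ import annotations

import io as _stdio
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__

logger = logging.getLogger(__name__)

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, normalized to DNA uppercase."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated collection of gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set with empty name")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass(frozen=True)
class ProbeMap:
    """Mapping of one microarray probe to its transcript and gene."""

    probe_id: str
    transcript_id: str
    gene_id: str


def normalize_sequence(raw: str, *, where: str = "") -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T.

    Raises :class:`FormatError`, naming the offending position, on any
    character outside ACGTUN.
    """
    seq = raw.upper().replace("U", "T")
    if not _VALID_SEQ.match(seq):
        for pos, ch in enumerate(seq, start=1):
            if ch not in "ACGTN":
                raise FormatError(
                    f"invalid character {ch!r} at position {pos}{where}"
                )
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Record ids are the first whitespace-delimited token of the header;
    the remainder is kept as the description.  Sequences are normalized
    to DNA uppercase (U→T).  Duplicate ids, empty sequences and
    characters outside ACGTUN are hard errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        seq = normalize_sequence(raw, where=f" of record {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, one line per sequence."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n" + rec.seq + "\n")


# ---------------------------------------------------------------------------
# small-RNA count tables


@dataclass
class MiRNACountTable:
    """Integer read counts per miRNA for paired IP and Total libraries.

    ``counts`` is indexed by miRNA name with columns ``IP_<r>`` and
    ``TOTAL_<r>`` for replicate indices ``r``; every IP library has a
    Total partner with the same index.
    """

    counts: pd.DataFrame
    replicates: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        ip = sorted(
            int(c.split("_", 1)[1]) for c in self.counts.columns if c.startswith("IP_")
        )
        total = sorted(
            int(c.split("_", 1)[1])
            for c in self.counts.columns
            if c.startswith("TOTAL_")
        )
        if not ip or ip != total:
            raise FormatError(
                f"unmatched IP/TOTAL replicates: IP={ip}, TOTAL={total}"
            )
        self.replicates = tuple(ip)
        self.counts = self.counts[self.ip_columns + self.total_columns]

    @property
    def ip_columns(self) -> list[str]:
        return [f"IP_{r}" for r in self.replicates]

    @property
    def total_columns(self) -> list[str]:
        return [f"TOTAL_{r}" for r in self.replicates]

    @property
    def mirnas(self) -> pd.Index:
        return self.counts.index

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def read_count_table(path: str | Path) -> MiRNACountTable:
    """Read a tab-separated miRNA read-count table.

    The header names libraries ``IP_<r>`` / ``TOTAL_<r>``; the first
    column holds miRNA names; all cells must be non-negative integers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    for col in df.columns:
        if not (col.startswith("IP_") or col.startswith("TOTAL_")):
            raise FormatError(f"unexpected library column {col!r} in {path}")
    counts = pd.DataFrame(index=df.index)
    for col in df.columns:
        for row, cell in df[col].items():
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {cell!r} at row {row!r}, column {col!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"negative count {cell!r} at row {row!r}, column {col!r}"
                )
        counts[col] = df[col].astype(np.int64)
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise FormatError(f"duplicate miRNA id {dup!r} in {path}")
    return MiRNACountTable(counts)


def write_count_table(
    table: MiRNACountTable, path: str | Path, *, params: Mapping | None = None
) -> None:
    write_tsv(table.counts, path, index_label="mirna", params=params)


# ---------------------------------------------------------------------------
# probe-level microarray signal tables


@dataclass
class ProbeSignalTable:
    """Probe-level IP/Total microarray signals with detection flags.

    ``data`` is indexed by probe id with columns ``transcript``, ``gene``,
    ``platform`` and, for each replicate ``r``, ``IP_<r>``, ``TOTAL_<r>``,
    ``DETECT_IP_<r>`` and ``DETECT_TOTAL_<r>``.  A probe measured on one
    platform carries False detection flags (and NaN signal) at the
    replicates of the other platform.
    """

    data: pd.DataFrame
    replicates: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        reps = sorted(
            int(c.split("_")[1]) for c in self.data.columns if c.startswith("IP_")
        )
        for r in reps:
            for col in (f"TOTAL_{r}", f"DETECT_IP_{r}", f"DETECT_TOTAL_{r}"):
                if col not in self.data.columns:
                    raise FormatError(f"missing column {col!r}")
        if not reps:
            raise FormatError("no replicate signal columns found")
        self.replicates = tuple(reps)

    @property
    def probes(self) -> pd.Index:
        return self.data.index

    @property
    def platforms(self) -> list[str]:
        return sorted(self.data["platform"].unique())

    def replicate_platform(self, r: int) -> str:
        """Platform measured at replicate ``r`` (majority of finite signals)."""
        finite = self.data.loc[np.isfinite(self.data[f"TOTAL_{r}"]), "platform"]
        if finite.empty:
            raise FormatError(f"replicate {r} has no finite signals")
        return finite.mode().iloc[0]

    def platform_replicates(self, platform: str) -> list[int]:
        return [r for r in self.replicates if self.replicate_platform(r) == platform]


def read_probe_table(path: str | Path) -> ProbeSignalTable:
    """Read the probe signal TSV written by :func:`write_probe_table`."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    for col in df.columns:
        if col.startswith("DETECT_"):
            df[col] = df[col].astype(bool)
    return ProbeSignalTable(df)


def write_probe_table(
    table: ProbeSignalTable, path: str | Path, *, params: Mapping | None = None
) -> None:
    write_tsv(table.data, path, index_label="probe", params=params)


# ---------------------------------------------------------------------------
# gene sets


def read_gene_set(path: str | Path, name: str) -> GeneSet:
    """Read a one-identifier-per-line gene list.

    Blank lines and ``#`` comment lines are ignored; duplicates are
    dropped (their number is logged).  An empty resulting set is a hard
    error.
    """
    path = Path(path)
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line)
    members = frozenset(ids)
    dropped = len(ids) - len(members)
    if dropped:
        logger.info("gene set %s: dropped %d duplicate id(s)", name, dropped)
    if not members:
        raise FormatError(f"gene set file {path} yields an empty set")
    return GeneSet(name=name, members=members)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gene set {gene_set.name} ({len(gene_set)} genes)\n")
        for gene in sorted(gene_set.members):
            fh.write(gene + "\n")


# ---------------------------------------------------------------------------
# generic TSV plumbing


def provenance_line(params: Mapping | None = None) -> str:
    parts = [f"miriscip {__version__}"]
    if params:
        parts += [f"{k}={v}" for k, v in params.items()]
    return "# " + " ".join(parts)


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    *,
    index_label: str | None = None,
    params: Mapping | None = None,
) -> None:
    """Write a DataFrame as strict TSV with a provenance comment line."""
    buf = _stdio.StringIO()
    df.to_csv(buf, sep="\t", index_label=index_label)
    with open(path, "w") as fh:
        fh.write(provenance_line(params) + "\n")
        fh.write(buf.getvalue())


def read_tsv(path: str | Path, *, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")
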