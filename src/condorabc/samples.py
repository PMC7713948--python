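"""Heterochronous sample handling: FASTA + metadata I/O, temporal strata,
and collapsing aligned mtDNA sequences into haplotypes.

The observational unit is an aligned mtDNA sequence with a collection year,
coordinates, and a regional label.  Collection years are binned into a
``historical`` and a ``contemporary`` period around a configurable breakpoint
(default 1950, the midpoint of the gap between museum and modern sampling
campaigns).  Two alignment partitions are carried by default: a 145 bp
mitochondrial Control-region fragment followed by a 165 bp 12S rRNA fragment,
concatenated into 310 bp haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seqarray import encode

logger = logging.getLogger(__name__)

HISTORICAL = "historical"
CONTEMPORARY = "contemporary"
DEFAULT_BREAKPOINT = 1950

#: default partitions: (name, start, length), half-open 0-based column spans
DEFAULT_PARTITIONS = (("control_region", 0, 145), ("s12", 145, 165))

METADATA_COLUMNS = ("sample_id", "year", "latitude", "longitude", "region")


def assign_period(year: int, breakpoint_year: int = DEFAULT_BREAKPOINT) -> str:
    """Bin a collection year: ``year < breakpoint`` is historical, else
    contemporary (the breakpoint year itself counts as contemporary)."""
    return HISTORICAL if year < breakpoint_year else CONTEMPORARY


@dataclass(frozen=True)
class SampleRecord:
    """One aligned sequence with its collection metadata."""

    sample_id: str
    year: int
    latitude: float
    longitude: float
    region: str
    sequence: str
    period: str = ""

    def __post_init__(self):
        if not 1800 <= self.year <= 2100:
            raise ValueError(f"{self.sample_id}: year {self.year} outside [1800, 2100]")
        if not self.period:
            object.__setattr__(self, "period", assign_period(self.year))

    @property
    def has_ambiguity(self) -> bool:
        return any(c in "Nn-" for c in self.sequence)


@dataclass
class SampleSet:
    """An ordered collection of equal-length :class:`SampleRecord` plus the
    partition layout of the alignment."""

    records: list[SampleRecord]
    partitions: tuple = DEFAULT_PARTITIONS

    def __post_init__(self):
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        total = lengths.pop() if lengths else sum(p[2] for p in self.partitions)
        pos = 0
        for name, start, plen in self.partitions:
            if start != pos:
                raise ValueError(f"partition {name} starts at {start}, expected {pos}")
            pos += plen
        if self.records and pos != total:
            raise ValueError(
                f"partitions tile {pos} columns but alignment is {total} columns"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence) if self.records else sum(
            p[2] for p in self.partitions
        )

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def matrix(self) -> np.ndarray:
        """uint8 matrix of the alignment (rows follow record order)."""
        return encode(self.sequences())

    def subset(self, predicate) -> "SampleSet":
        return SampleSet([r for r in self.records if predicate(r)], self.partitions)

    def by_period(self, period: str) -> "SampleSet":
        return self.subset(lambda r: r.period == period)

    def drop_ambiguous(self) -> "SampleSet":
        """Remove records containing N or gap characters (partial haplotypes
        are excluded from haplotype and pairwise statistics)."""
        dropped = [r.sample_id for r in self.records if r.has_ambiguity]
        if dropped:
            logger.info("excluding %d sample(s) with ambiguous bases: %s",
                        len(dropped), ", ".join(dropped))
        return self.subset(lambda r: not r.has_ambiguity)

    def to_metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "year": [r.year for r in self.records],
                "latitude": [r.latitude for r in self.records],
                "longitude": [r.longitude for r in self.records],
                "region": [r.region for r in self.records],
                "period": [r.period for r in self.records],
            }
        )


@dataclass
class HaplotypeTable:
    """Distinct sequences with counts stratified by (period, region).

    ``haplotypes`` preserves first-seen order and ids are H1, H2, ... in that
    order.  ``counts`` maps (haplotype_id, period, region) -> count.
    """

    haplotypes: list[tuple[str, str]]
    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)

    @property
    def n_H(self) -> int:
        return len(self.haplotypes)

    @property
    def n_samples(self) -> int:
        return sum(self.counts.values())

    def haplotype_counts(self, period: str | None = None,
                         region: str | None = None) -> dict[str, int]:
        """Marginal per-haplotype counts, optionally restricted to a stratum."""
        out: dict[str, int] = {}
        for (hap, per, reg), c in self.counts.items():
            if period is not None and per != period:
                continue
            if region is not None and reg != region:
                continue
            out[hap] = out.get(hap, 0) + c
        return out

    def periods(self) -> list[str]:
        seen = []
        for (_, per, _) in self.counts:
            if per not in seen:
                seen.append(per)
        # historical sorts before contemporary when both present
        order = {HISTORICAL: 0, CONTEMPORARY: 1}
        return sorted(seen, key=lambda p: (order.get(p, 2), p))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"haplotype": hap, "period": per, "region": reg, "count": c}
            for (hap, per, reg), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["haplotype", "period", "region", "count"])


def collapse_haplotypes(sample_set: SampleSet) -> HaplotypeTable:
    """Collapse full-length identical sequences into haplotypes.

    Records containing ambiguous characters are excluded (and logged) before
    collapsing.  Haplotype ids are assigned in first-seen record order.
    """
    clean = sample_set.drop_ambiguous()
    seq_to_id: dict[str, str] = {}
    haplotypes: list[tuple[str, str]] = []
    counts: dict[tuple[str, str, str], int] = {}
    for rec in clean:
        hid = seq_to_id.get(rec.sequence)
        if hid is None:
            hid = f"H{len(haplotypes) + 1}"
            seq_to_id[rec.sequence] = hid
            haplotypes.append((hid, rec.sequence))
        key = (hid, rec.period, rec.region)
        counts[key] = counts.get(key, 0) + 1
    return HaplotypeTable(haplotypes, counts)


def read_samples(
    fasta_path: str | Path,
    metadata_path: str | Path,
    breakpoint_year: int = DEFAULT_BREAKPOINT,
    partitions: tuple = DEFAULT_PARTITIONS,
) -> SampleSet:
    """Read an aligned FASTA and a CSV metadata table into a SampleSet.

    The CSV requires columns ``sample_id,year,latitude,longitude,region`` and
    may carry an optional ``period`` override column.  FASTA ids must match
    metadata ids one-to-one; record order follows the metadata table.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"no records in FASTA {fasta_path}")
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str})
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    meta_ids = list(meta["sample_id"])
    extra_fasta = sorted(set(seqs) - set(meta_ids))
    extra_meta = sorted(set(meta_ids) - set(seqs))
    if extra_fasta or extra_meta:
        raise ValueError(
            "FASTA/metadata id mismatch: "
            f"in FASTA only {extra_fasta}; in metadata only {extra_meta}"
        )
    if len(meta_ids) != len(set(meta_ids)):
        raise ValueError("duplicate sample_id in metadata")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    records = []
    has_period = "period" in meta.columns
    for row in meta.itertuples(index=False):
        period = getattr(row, "period") if has_period else assign_period(
            int(row.year), breakpoint_year
        )
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                year=int(row.year),
                latitude=float(row.latitude),
                longitude=float(row.longitude),
                region=str(row.region),
                sequence=seqs[row.sample_id],
                period=period,
            )
        )
    return SampleSet(records, partitions)


def write_samples(sample_set: SampleSet, fasta_path: str | Path,
                  metadata_path: str | Path) -> None:
    """Write a SampleSet back to FASTA + CSV (round-trips with read_samples)."""
    recs = [
        SeqRecord(Seq(r.sequence), id=r.sample_id, description="")
        for r in sample_set.records
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    sample_set.to_metadata_frame().to_csv(metadata_path, index=False)
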