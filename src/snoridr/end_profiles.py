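"""Read-end counting over an rRNA reference.

Converts aligned short-read records (BED6 or minimal SAM) into per-position
5'/3'-end count profiles and per-bond cleavage profiles. These profiles are
the raw material of both the RiboMethSeq methylation score and the
HydraPsiSeq pseudouridylation score.

Coordinate conventions
----------------------
Bases are 1-based; BED input is 0-based half-open. A read aligned at BED
``(start, end)`` has its 5'-end at base ``start + 1`` and its 3'-end at base
``end``. Internucleotide bond ``i`` joins bases ``i`` and ``i + 1``
(bonds ``1 .. L-1``); the combined cleavage count of bond ``i`` is
``c(i) = n3(i) + n5(i+1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: CIGAR operations compatible with exact end-position recovery
#: (M, =, X). Anything gapped or clipped makes the fragment ends ambiguous.
_UNGAPPED_CIGAR_OPS = {0, 7, 8}


@dataclass
class Alignments:
    """A collection of aligned segments on one or more references.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive (BED
    convention), so ``end - start`` is the aligned length.
    """

    ref_ids: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.end <= self.start):
            raise ValueError("all segments must satisfy start < end")
        if np.any(self.start < 0):
            raise ValueError("negative start coordinate")

    def __len__(self) -> int:
        return self.start.size

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    @classmethod
    def single_reference(cls, ref_id: str, start, end, strand=None) -> "Alignments":
        start = np.asarray(start, dtype=np.int64)
        if strand is None:
            strand = np.full(start.size, "+", dtype="U1")
        return cls(
            ref_ids=np.full(start.size, ref_id, dtype=object),
            start=start,
            end=np.asarray(end, dtype=np.int64),
            strand=np.asarray(strand, dtype="U1"),
        )

    def subset(self, mask: np.ndarray) -> "Alignments":
        return Alignments(self.ref_ids[mask], self.start[mask], self.end[mask], self.strand[mask])

    def to_bed(self, path, names=None) -> None:
        """Write BED6 (name column synthesized when absent, score 0)."""
        with open(path, "w") as fh:
            for i in range(len(self)):
                name = names[i] if names is not None else f"r{i}"
                fh.write(f"{self.ref_ids[i]}\t{self.start[i]}\t{self.end[i]}\t{name}\t0\t{self.strand[i]}\n")


@dataclass
class EndCountProfile:
    """Per-position read-end counts; arrays are indexed by 1-based base
    position (index 0 unused)."""

    ref_id: str
    n5: np.ndarray
    n3: np.ndarray

    @property
    def length(self) -> int:
        return self.n5.size - 1

    def to_frame(self) -> pd.DataFrame:
        pos = np.arange(1, self.length + 1)
        return pd.DataFrame({"position": pos, "n5": self.n5[1:], "n3": self.n3[1:]})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CleavageProfile:
    """Combined cleavage counts per internucleotide bond, indexed by bond
    number 1..L-1 (index 0 unused)."""

    ref_id: str
    c: np.ndarray

    @property
    def n_bonds(self) -> int:
        return self.c.size - 1

    def to_frame(self) -> pd.DataFrame:
        bond = np.arange(1, self.n_bonds + 1)
        return pd.DataFrame({"bond": bond, "c": self.c[1:]})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _parse_bed(path, reference_lengths) -> Alignments:
    refs, starts, ends, strands = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: invalid strand {strand!r}")
            if reference_lengths is not None:
                if chrom not in reference_lengths:
                    raise ValueError(f"{path}: line {lineno}: unknown reference id {chrom!r}")
                if end > reference_lengths[chrom]:
                    raise ValueError(
                        f"{path}: line {lineno}: end {end} exceeds reference length {reference_lengths[chrom]}"
                    )
            refs.append(chrom)
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    if not refs:
        logger.warning("%s: no alignments parsed (empty file)", path)
    return Alignments(
        ref_ids=np.array(refs, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype="U1"),
    )


def _parse_sam(path, reference_lengths) -> Alignments:
    refs, starts, ends, strands = [], [], [], []
    n_rejected = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            ops = {op for op, _ in (rec.cigartuples or [])}
            if not ops or not ops <= _UNGAPPED_CIGAR_OPS:
                # gapped/clipped alignments have ambiguous fragment ends
                n_rejected += 1
                continue
            ref = rec.reference_name
            if reference_lengths is not None and ref not in reference_lengths:
                raise ValueError(f"{path}: unknown reference id {ref!r} (read {rec.query_name})")
            refs.append(ref)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
            strands.append("-" if rec.is_reverse else "+")
    if n_rejected:
        logger.warning("%s: rejected %d gapped/clipped SAM records", path, n_rejected)
    if not refs:
        logger.warning("%s: no alignments parsed", path)
    return Alignments(
        ref_ids=np.array(refs, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype="U1"),
    )


def read_alignments(path, format: str = "bed", reference_lengths: dict | None = None) -> Alignments:
    """Parse aligned read records.

    Parameters
    ----------
    path:
        BED6 or SAM file.
    format:
        ``"bed"`` or ``"sam"``. SAM support is deliberately minimal:
        ungapped primary alignments only (records with I/D/N/S CIGAR
        operations are rejected with a logged count), because read-end
        positions are only exact for ungapped short fragments.
    reference_lengths:
        Optional ``{ref_id: length}`` used to validate coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bed":
        return _parse_bed(path, reference_lengths)
    if format == "sam":
        return _parse_sam(path, reference_lengths)
    raise ValueError(f"unknown alignment format {format!r} (expected 'bed' or 'sam')")


def filter_short_reads(alignments: Alignments, max_len: int = 40) -> Alignments:
    """Keep reads strictly shorter than ``max_len`` nucleotides.

    This is the RMS protocol's read-selection rule: only short fragments
    capture the exact positions of both ends. HPS counting uses 5'-ends
    regardless of length and does not apply this filter.
    """
    mask = alignments.lengths < max_len
    if not mask.any() and len(alignments):
        logger.warning("filter_short_reads: no reads shorter than %d nt remain", max_len)
    return alignments.subset(mask)


def count_ends(alignments: Alignments, ref_length: int) -> EndCountProfile:
    """Tally read 5'- and 3'-ends per 1-based reference position.

    Minus-strand segments are discarded (with a logged count): the rRNA
    reference is a single-stranded sense sequence.
    """
    uniq = set(alignments.ref_ids.tolist())
    if len(uniq) > 1:
        raise ValueError(f"count_ends expects a single reference, got {sorted(uniq)}")
    ref_id = uniq.pop() if uniq else ""
    plus = alignments.strand == "+"
    n_minus = int((~plus).sum())
    if n_minus:
        logger.warning("count_ends: discarded %d minus-strand segments", n_minus)
    start = alignments.start[plus]
    end = alignments.end[plus]
    if start.size and end.max() > ref_length:
        raise ValueError(f"segment end {end.max()} exceeds reference length {ref_length}")
    n5 = np.bincount(start + 1, minlength=ref_length + 1).astype(np.int64)
    n3 = np.bincount(end, minlength=ref_length + 1).astype(np.int64)
    return EndCountProfile(ref_id=ref_id, n5=n5, n3=n3)


def bond_profile(profile: EndCountProfile) -> CleavageProfile:
    """Combined cleavage count per bond: ``c(i) = n3(i) + n5(i+1)``.

    Read ends at the molecule boundaries (5'-end at base 1, 3'-end at base
    L) correspond to no internal bond and are excluded.
    """
    L = profile.length
    c = np.zeros(L, dtype=np.int64)  # index = bond 1..L-1, index 0 unused
    c[1:] = profile.n3[1:L] + profile.n5[2 : L + 1]
    return CleavageProfile(ref_id=profile.ref_id, c=c)
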