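"""Charge patterning of intrinsically disordered regions (IDRs).

Implements the Das-Pappu style charge descriptors used to characterize
lysine-rich (KKE/D) domains of nucleolar proteins:

* per-residue charge fractions ``f+``, ``f-``; FCR (fraction of charged
  residues, ``f+ + f-``); NCPR (net charge per residue, ``f+ - f-``);
  NCPD (net charge per domain, the integer net charge);
* the kappa charge-segregation index in [0, 1] (0 = perfectly mixed
  charges, 1 = fully segregated charge blocks), from blob-wise charge
  asymmetry at blob sizes 5 and 6 normalized by the maximally segregated
  rearrangement of the same composition;
* a diagram-of-states classification (weak / boundary / strong
  polyampholyte / strong polyelectrolyte);
* detection of lysine-doublet (KK) repeat segments spaced by polar
  residues (E/D/H/S), the hallmark of KKE/D domains;
* a proteome scan joining disorder-segment annotations, sequences and
  abundances into one feature table.

Charges: K, R = +1; D, E = -1; H = 0 by default (configurable); X is
tolerated as a neutral unknown with a warning.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_SPACERS = frozenset("EDHS")


def charge_array(sequence: str, his_charge: float = 0.0) -> np.ndarray:
    """Per-residue charge vector (K/R +1, D/E -1, H configurable)."""
    charges = np.zeros(len(sequence))
    n_unknown = 0
    for i, aa in enumerate(sequence.upper()):
        if aa in "KR":
            charges[i] = 1.0
        elif aa in "DE":
            charges[i] = -1.0
        elif aa == "H":
            charges[i] = his_charge
        elif aa == "X":
            n_unknown += 1
        elif aa not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
    if n_unknown:
        logger.warning("sequence contains %d 'X' residues (treated as uncharged)", n_unknown)
    return charges


@dataclass
class ChargeFeatures:
    length: int
    fplus: float
    fminus: float
    fcr: float  # fplus + fminus
    ncpr: float  # fplus - fminus
    ncpd: int  # integer net charge of the whole domain


def charge_features(sequence: str, his_charge: float = 0.0) -> ChargeFeatures:
    """FCR / NCPR / NCPD of a sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    c = charge_array(sequence, his_charge)
    L = c.size
    fplus = float(np.clip(c, 0, None).sum() / L)
    fminus = float(-np.clip(c, None, 0).sum() / L)
    ncpr = fplus - fminus
    return ChargeFeatures(
        length=L,
        fplus=fplus,
        fminus=fminus,
        fcr=fplus + fminus,
        ncpr=ncpr,
        ncpd=int(round(ncpr * L)),
    )


def windowed_ncpr(sequence: str, window: int = 5, his_charge: float = 0.0) -> np.ndarray:
    """Sliding-window net charge per residue (step 1, reported at window
    centers); profile length is ``L - window + 1``."""
    c = charge_array(sequence, his_charge)
    if c.size < window:
        raise ValueError(f"sequence of length {c.size} shorter than window {window}")
    kernel = np.ones(window) / window
    return np.convolve(c, kernel, mode="valid")


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

def _sigma(fplus: float, fminus: float) -> float:
    """Charge asymmetry (f+ - f-)^2 / (f+ + f-); 0 for a chargeless blob."""
    tot = fplus + fminus
    if tot == 0:
        return 0.0
    return (fplus - fminus) ** 2 / tot


def _delta(signs: np.ndarray, g: int) -> float:
    """Mean squared deviation of blob charge asymmetry from the sequence
    asymmetry, over all overlapping blobs of size g."""
    n = signs.size
    pos = (signs > 0).astype(float)
    neg = (signs < 0).astype(float)
    sigma_seq = _sigma(pos.mean(), neg.mean())
    cpos = np.convolve(pos, np.ones(g), mode="valid") / g
    cneg = np.convolve(neg, np.ones(g), mode="valid") / g
    tot = cpos + cneg
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_blob = np.where(tot > 0, (cpos - cneg) ** 2 / np.where(tot > 0, tot, 1.0), 0.0)
    return float(np.mean((sigma_blob - sigma_seq) ** 2))


def _canonical_segregated(n_pos: int, n_neg: int, n_neu: int):
    """Candidate maximally segregated sign patterns of a composition.

    All arrangements with the positive and the negative residues each in
    one contiguous block: the neutral residues either split around the two
    adjacent charge blocks (every prefix/suffix split, both block orders)
    or form a single block between them.
    """
    P = [1] * n_pos
    M = [-1] * n_neg
    for first, second in ((P, M), (M, P)):
        for k in range(n_neu + 1):
            yield np.array([0] * k + first + second + [0] * (n_neu - k), dtype=float)
        if n_neu:
            yield np.array(first + [0] * n_neu + second, dtype=float)


def delta_max(n_pos: int, n_neg: int, n_neu: int, g: int) -> float:
    """Delta of the most segregated canonical rearrangement of a composition.

    This is the standard normalizer for kappa: the charge blocks are made
    contiguous and the neutral residues are placed around or between them,
    and the largest delta over those arrangements is taken. It is a
    construction, not a proven maximum -- for some short compositions a
    non-blocky permutation exceeds it (the kappa ratio is therefore clamped
    to 1)."""
    best = 0.0
    for arrangement in _canonical_segregated(n_pos, n_neg, n_neu):
        best = max(best, _delta(arrangement, g))
    return best


@dataclass
class KappaComputation:
    blob_sizes: tuple
    delta: dict
    delta_max: dict
    kappa: float
    reason: str | None = None


def kappa(sequence: str, blobs: tuple = (5, 6), his_charge: float = 0.0) -> KappaComputation:
    """Charge-segregation index kappa.

    ``kappa = mean_g(delta_g / delta_max_g)`` over blob sizes ``g`` (5 and
    6 by default), with each ratio clamped to 1 (the canonical
    ``delta_max`` construction can be undershot by exotic short
    arrangements). Undefined (NaN, with a reason code) when the sequence is
    shorter than 6 residues, carries no charge, or carries only one charge
    sign -- segregation is meaningless in those cases. Blob sizes whose
    ``delta_max`` is zero (no rearrangement of the composition changes the
    blob asymmetry, e.g. blob size = sequence length) are skipped.
    """
    c = charge_array(sequence, his_charge)
    signs = np.sign(c)
    if c.size < 6:
        return KappaComputation(blobs, {}, {}, math.nan, "too_short")
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    n_neu = signs.size - n_pos - n_neg
    if n_pos + n_neg == 0:
        return KappaComputation(blobs, {}, {}, math.nan, "no_charges")
    if n_pos == 0 or n_neg == 0:
        return KappaComputation(blobs, {}, {}, math.nan, "single_charge_sign")
    deltas, dmaxes, ratios = {}, {}, []
    for g in blobs:
        if g > signs.size:
            continue
        d = _delta(signs, g)
        dm = delta_max(n_pos, n_neg, n_neu, g)
        deltas[g], dmaxes[g] = d, dm
        if dm > 0:
            ratios.append(min(d / dm, 1.0))
    if not ratios:
        return KappaComputation(blobs, deltas, dmaxes, math.nan, "degenerate_delta_max")
    return KappaComputation(blobs, deltas, dmaxes, float(np.mean(ratios)))


# ---------------------------------------------------------------------------
# diagram of states
# ---------------------------------------------------------------------------

WEAK_FCR = 0.25
STRONG_FCR = 0.35
#: NCPR boundary separating strong polyampholytes from polyelectrolytes.
#: 0.3 is the threshold printed alongside the FCR > 0.35 rule; the
#: canonical diagram-of-states value 0.35 is available via
#: ``ncpr_boundary=0.35``.
NCPR_BOUNDARY = 0.3


def diagram_of_states(features: ChargeFeatures, ncpr_boundary: float = NCPR_BOUNDARY) -> str:
    """Diagram-of-states class label from FCR and NCPR.

    weak (FCR < 0.25); boundary (0.25 <= FCR <= 0.35); strong
    polyampholyte (FCR > 0.35, |NCPR| <= boundary); positive/negative
    strong polyelectrolyte (FCR > 0.35, |NCPR| > boundary).
    """
    fcr, ncpr = features.fcr, features.ncpr
    if fcr < WEAK_FCR:
        return "weak"
    if fcr <= STRONG_FCR:
        return "boundary"
    if abs(ncpr) <= ncpr_boundary:
        return "strong polyampholyte"
    return "positive strong polyelectrolyte" if ncpr > 0 else "negative strong polyelectrolyte"


# ---------------------------------------------------------------------------
# IDR extraction and KKE/D repeat detection
# ---------------------------------------------------------------------------

@dataclass
class IDRSegment:
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    abundance: float = math.nan


def extract_idrs(
    disorder: pd.DataFrame,
    sequences: dict[str, str],
    abundance: pd.DataFrame | None = None,
    min_len: int = 30,
) -> list[IDRSegment]:
    """Join a disorder-segment table to sequences and abundances.

    Segments strictly longer than ``min_len`` residues are retained.
    Coordinates are 1-based inclusive and validated against the protein
    length; ids missing from the sequence set are skipped with a warning;
    missing abundances become NaN.
    """
    abundance_map: dict[str, float] = {}
    if abundance is not None:
        abundance_map = dict(zip(abundance["protein_id"], abundance["abundance"].astype(float)))
    out: list[IDRSegment] = []
    for _, row in disorder.iterrows():
        pid = str(row["protein_id"])
        start, end = int(row["start"]), int(row["end"])
        if pid not in sequences:
            logger.warning("extract_idrs: %s absent from FASTA, row skipped", pid)
            continue
        seq = sequences[pid]
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(f"segment {pid}:{start}-{end} outside protein length {len(seq)}")
        if end - start + 1 <= min_len:
            continue
        out.append(
            IDRSegment(
                protein_id=pid,
                start=start,
                end=end,
                sequence=seq[start - 1 : end],
                abundance=abundance_map.get(pid, math.nan),
            )
        )
    return out


@dataclass
class KkeSegment:
    start: int  # 1-based position of the first K of the first doublet
    end: int  # 1-based position of the last K of the last doublet
    n_doublets: int
    spacer_composition: dict


def detect_kke_repeats(
    sequence: str,
    spacer_set: frozenset = DEFAULT_SPACERS,
    max_spacer: int = 3,
    min_doublets: int = 3,
) -> list[KkeSegment]:
    """Find lysine-doublet (KK) repeat segments.

    KK doublets are located greedily left to right without overlap (so
    ``KKK`` holds a single doublet). Consecutive doublets chain into one
    segment when separated by 1..``max_spacer`` residues drawn entirely
    from ``spacer_set`` (adjacent doublets -- zero spacer -- do not chain:
    they are one lysine run, not a doublet repeat). Chains of at least
    ``min_doublets`` doublets are reported, bounded by their first and
    last doublet.
    """
    seq = sequence.upper()
    doublets = []  # 0-based start of each KK
    i = 0
    while i < len(seq) - 1:
        if seq[i] == "K" and seq[i + 1] == "K":
            doublets.append(i)
            i += 2
        else:
            i += 1

    segments: list[KkeSegment] = []
    chain: list[int] = []

    def flush() -> None:
        if len(chain) >= min_doublets:
            spacers = Counter()
            for a, b in zip(chain, chain[1:]):
                spacers.update(seq[a + 2 : b])
            segments.append(
                KkeSegment(
                    start=chain[0] + 1,
                    end=chain[-1] + 2,
                    n_doublets=len(chain),
                    spacer_composition=dict(spacers),
                )
            )

    for d in doublets:
        if chain:
            gap = seq[chain[-1] + 2 : d]
            if 1 <= len(gap) <= max_spacer and all(aa in spacer_set for aa in gap):
                chain.append(d)
                continue
            flush()
        chain = [d]
    flush()
    return segments


# ---------------------------------------------------------------------------
# proteome scan
# ---------------------------------------------------------------------------

def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def proteome_scan(
    sequences: dict[str, str],
    disorder: pd.DataFrame,
    abundance: pd.DataFrame | None = None,
    min_len: int = 30,
    his_charge: float = 0.0,
    ncpr_boundary: float = NCPR_BOUNDARY,
) -> pd.DataFrame:
    """Charge-feature table over every annotated IDR of a proteome.

    One row per IDR longer than ``min_len``: f+, f-, FCR, NCPR, NCPD,
    kappa (NaN with reason when undefined), diagram-of-states class,
    KKE/D repeat segments (count, maximal doublet number, coordinates of
    the best segment in protein coordinates) and protein abundance.
    Output order is (protein_id, start), independent of input order.
    """
    idrs = extract_idrs(disorder, sequences, abundance, min_len=min_len)
    rows = []
    for idr in idrs:
        feats = charge_features(idr.sequence, his_charge)
        kap = kappa(idr.sequence, his_charge=his_charge)
        segs = detect_kke_repeats(idr.sequence)
        best = max(segs, key=lambda s: s.n_doublets) if segs else None
        rows.append(
            {
                "protein_id": idr.protein_id,
                "start": idr.start,
                "end": idr.end,
                "length": feats.length,
                "fplus": feats.fplus,
                "fminus": feats.fminus,
                "fcr": feats.fcr,
                "ncpr": feats.ncpr,
                "ncpd": feats.ncpd,
                "kappa": kap.kappa,
                "kappa_reason": kap.reason,
                "state_class": diagram_of_states(feats, ncpr_boundary),
                "n_kke_segments": len(segs),
                "kke_doublets": best.n_doublets if best else 0,
                "kke_start": idr.start + best.start - 1 if best else pd.NA,
                "kke_end": idr.start + best.end - 1 if best else pd.NA,
                "abundance": idr.abundance,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["protein_id", "start"], kind="mergesort", ignore_index=True)
    return out
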