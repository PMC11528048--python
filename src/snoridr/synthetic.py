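"""Synthetic-data generators for the whole pipeline.

Every input the analysis consumes is generated here with a co-emitted truth
record, so each downstream score has a recovery target:

* an rRNA-like reference sequence and a table of planted Nm / Psi sites
  with true modified fractions;
* RiboMethSeq-style fragments (alkaline-hydrolysis model: every
  internucleotide bond carries a lognormal cleavage propensity, attenuated
  by ``1 - f`` at 2'-O-methylated bases) and HydraPsiSeq-style 5'-end reads
  (hydrazine model: uridines cleave ``u_rate / bg_rate`` times more often
  than A/C/G, attenuated by ``1 - f`` at pseudouridylated positions);
* a small proteome with planted lysine-doublet (KKE/D-like) IDR segments,
  a disorder-segment table and lognormal abundances;
* qPCR / iBAQ / ROI fixture tables for the enrichment statistics.

All generators are pure functions of (inputs, seed): a fixed
:class:`~snoridr.config.SimulationConfig` reproduces byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import SimulationConfig
from .end_profiles import Alignments

logger = logging.getLogger(__name__)

# salts for per-stage independent random streams
_SALT_REFERENCE = 11
_SALT_SITES = 23
_SALT_RMS = 37
_SALT_HPS = 41
_SALT_PROTEOME = 53
_SALT_FIXTURES = 67

RNA_ALPHABET = np.array(list("ACGU"))

#: background amino-acid frequencies loosely matching the yeast proteome
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array(
    [0.055, 0.013, 0.058, 0.065, 0.045, 0.050, 0.022, 0.066, 0.073, 0.096,
     0.021, 0.061, 0.044, 0.040, 0.044, 0.090, 0.059, 0.056, 0.010, 0.034]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


# ---------------------------------------------------------------------------
# reference and modification sites
# ---------------------------------------------------------------------------

def gen_reference(config: SimulationConfig, ref_id: str = "synthetic_rRNA") -> SeqRecord:
    """Random RNA reference sequence over {A, C, G, U}.

    Base composition is uniform; real rRNA structure is irrelevant to
    end-count statistics, which depend only on base identity (HPS) and
    position (RMS).
    """
    rng = config.rng(_SALT_REFERENCE)
    seq = "".join(rng.choice(RNA_ALPHABET, size=config.ref_length))
    return SeqRecord(Seq(seq), id=ref_id, description="synthetic rRNA reference")


def write_reference_fasta(record: SeqRecord, path) -> None:
    """Write with the DNA alphabet (U -> T), as aligner references are DNA."""
    dna = SeqRecord(Seq(str(record.seq).replace("U", "T")), id=record.id, description=record.description)
    SeqIO.write([dna], str(path), "fasta")


def read_reference_fasta(path) -> SeqRecord:
    """Read a reference FASTA back as RNA (T -> U)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    record.seq = Seq(str(record.seq).upper().replace("T", "U"))
    return record


def gen_sites(reference: SeqRecord, config: SimulationConfig) -> pd.DataFrame:
    """Plant Nm and Psi sites on the reference.

    Returns a modification-site table with columns ``position`` (1-based),
    ``mod_type`` (``Nm`` | ``Psi``) and ``true_fraction``. Psi sites fall
    only on U; all sites keep a pairwise distance of at least
    ``config.min_spacing`` (default 5 nt, so no +/-2 scoring window spans
    two sites) and a 12-nt margin from the reference ends (room for the
    10-nt HPS normalization window).
    """
    rng = config.rng(_SALT_SITES)
    seq = np.array(list(str(reference.seq)))
    L = seq.size
    margin = 12
    if L < 2 * margin + (config.n_nm_sites + config.n_psi_sites) * config.min_spacing:
        raise ValueError(
            f"reference of length {L} cannot host {config.n_nm_sites + config.n_psi_sites} "
            f"sites at spacing {config.min_spacing}"
        )
    u_positions = np.where(seq == "U")[0] + 1
    u_positions = u_positions[(u_positions > margin) & (u_positions <= L - margin)]
    if config.n_psi_sites > u_positions.size:
        raise ValueError(
            f"requested {config.n_psi_sites} Psi sites but only {u_positions.size} eligible U positions"
        )

    taken: list[int] = []

    def place(candidates: np.ndarray, n: int, label: str) -> list[int]:
        order = rng.permutation(candidates)
        chosen: list[int] = []
        if n == 0:
            return chosen
        for pos in order:
            if all(abs(int(pos) - t) >= config.min_spacing for t in taken):
                chosen.append(int(pos))
                taken.append(int(pos))
                if len(chosen) == n:
                    return chosen
        raise ValueError(f"could not place {n} {label} sites at spacing {config.min_spacing}")

    psi = place(u_positions, config.n_psi_sites, "Psi")
    all_positions = np.arange(margin + 1, L - margin + 1)
    nm = place(all_positions, config.n_nm_sites, "Nm")

    lo, hi = config.fraction_range
    rows = pd.DataFrame(
        {
            "position": psi + nm,
            "mod_type": ["Psi"] * len(psi) + ["Nm"] * len(nm),
            "true_fraction": rng.uniform(lo, hi, size=len(psi) + len(nm)),
        }
    )
    return rows.sort_values("position", ignore_index=True)


# ---------------------------------------------------------------------------
# RiboMethSeq fragment simulator
# ---------------------------------------------------------------------------

@dataclass
class RmsTruth:
    """Simulator bookkeeping: per-position end tallies and bond weights."""

    n5: np.ndarray  # 1-based base position, index 0 unused
    n3: np.ndarray
    bond_weight: np.ndarray  # 1-based bond index, index 0 unused
    n_reads: int


def simulate_rms(
    reference: SeqRecord,
    sites: pd.DataFrame,
    config: SimulationConfig,
    replicate: int = 0,
) -> tuple[Alignments, RmsTruth]:
    """Simulate alkaline-hydrolysis fragments for RiboMethSeq.

    Each bond ``i`` (joining bases ``i`` and ``i+1``) carries a cleavage
    propensity ``w_i = exp(N(0, propensity_sd))``; an Nm site at base ``n``
    with true fraction ``f`` attenuates bond ``n`` (the bond 3' of the
    methylated ribose) by ``1 - f``. A fragment is delimited by two cleavage
    events ``(a, b)`` with length ``b - a`` inside ``read_length_range``;
    fragment pairs are sampled with probability proportional to
    ``w_a * w_b`` via vectorized rejection sampling, so the expected end
    count at a fully protected bond is zero.

    Returns the simulated alignments (BED convention) and the simulator's
    own end tallies, which :func:`snoridr.end_profiles.count_ends` must
    recover exactly.
    """
    rng = config.rng(_SALT_RMS + 1000 * replicate)
    L = len(reference.seq)
    n_bonds = L - 1
    w = np.exp(rng.normal(0.0, config.propensity_sd, size=n_bonds))  # w[i] = bond i+1
    for _, row in sites.iterrows():
        if row["mod_type"] != "Nm":
            continue
        bond = int(row["position"])  # Nm at base n protects bond n
        if 1 <= bond <= n_bonds:
            w[bond - 1] *= 1.0 - float(row["true_fraction"])

    lmin, lmax = config.read_length_range
    n_reads = int(rng.poisson(config.depth * n_bonds / 2.0))

    # 5'-cleavage bond a must leave room for the shortest fragment
    a_weights = w.copy()
    a_weights[n_bonds - lmin :] = 0.0
    p_a = a_weights / a_weights.sum()
    w_max = w.max()

    starts = np.empty(n_reads, dtype=np.int64)
    ends = np.empty(n_reads, dtype=np.int64)
    got = 0
    bonds_idx = np.arange(1, n_bonds + 1)
    while got < n_reads:
        batch = max(4 * (n_reads - got), 1024)
        a = rng.choice(bonds_idx, size=batch, p=p_a)
        ell = rng.integers(lmin, lmax + 1, size=batch)
        b = a + ell
        ok = b <= n_bonds
        ok &= rng.random(batch) * w_max < np.where(ok, w[np.minimum(b, n_bonds) - 1], 0.0)
        a, b = a[ok], b[ok]
        take = min(a.size, n_reads - got)
        starts[got : got + take] = a[:take]  # 0-based start of base a+1
        ends[got : got + take] = b[:take]  # 0-based half-open end at base b
        got += take

    n5 = np.bincount(starts + 1, minlength=L + 1).astype(np.int64)
    n3 = np.bincount(ends, minlength=L + 1).astype(np.int64)
    bond_weight = np.zeros(n_bonds + 1)
    bond_weight[1:] = w
    truth = RmsTruth(n5=n5, n3=n3, bond_weight=bond_weight, n_reads=n_reads)
    aln = Alignments.single_reference(reference.id, starts, ends)
    return aln, truth


# ---------------------------------------------------------------------------
# HydraPsiSeq 5'-end simulator
# ---------------------------------------------------------------------------

@dataclass
class HpsTruth:
    n5: np.ndarray  # 1-based counted 5'-end position, index 0 unused
    propensity: np.ndarray  # 1-based cleaved-base propensity, index 0 unused
    n_reads: int


#: maximum fraction of U positions that may carry a Psi site -- beyond this
#: the median-U baseline of the PsiScore is no longer a valid proxy for the
#: unmodified cleavage level.
MAX_PSI_DENSITY = 0.20


def simulate_hps(
    reference: SeqRecord,
    sites: pd.DataFrame,
    config: SimulationConfig,
    replicate: int = 0,
) -> tuple[Alignments, HpsTruth]:
    """Simulate hydrazine/aniline cleavage reads for HydraPsiSeq.

    The cleavage propensity of base ``p`` is ``u_rate * (1 - f_p)`` when
    ``p`` is a uridine (``f_p`` its pseudouridylated fraction, 0 when
    unmodified) and ``bg_rate`` otherwise, times a lognormal position bias
    ``exp(N(0, propensity_sd))``. Each cleavage emits the 5'-end of the
    downstream fragment at the cleaved base plus ``config.hps_offset``
    (default 0: counted at the cleaved uridine itself; the scorer shares
    this convention).
    """
    rng = config.rng(_SALT_HPS + 1000 * replicate)
    L = len(reference.seq)
    seq = np.array(list(str(reference.seq)))
    psi = sites[sites["mod_type"] == "Psi"]
    n_u = int((seq == "U").sum())
    if n_u and len(psi) / n_u > MAX_PSI_DENSITY:
        raise ValueError(
            f"{len(psi)} Psi sites on {n_u} uridines exceeds the {MAX_PSI_DENSITY:.0%} density "
            "limit under which the median-U PsiScore baseline is valid"
        )
    frac = np.zeros(L + 1)
    for _, row in psi.iterrows():
        pos = int(row["position"])
        if seq[pos - 1] != "U":
            raise ValueError(f"Psi site at position {pos} is not a uridine")
        frac[pos] = float(row["true_fraction"])

    rho = np.where(seq == "U", config.u_rate, config.bg_rate).astype(float)
    rho *= 1.0 - frac[1:]  # only U positions carry nonzero frac
    rho *= np.exp(rng.normal(0.0, config.propensity_sd, size=L))

    n_reads = int(rng.poisson(config.depth * L))
    counts = rng.multinomial(n_reads, rho / rho.sum())  # counts[p-1] = cleavages at base p

    # counted 5'-end position = cleaved base + offset
    end5 = np.arange(1, L + 1) + config.hps_offset
    valid = (end5 >= 1) & (end5 <= L)
    counts = np.where(valid, counts, 0)
    n_reads = int(counts.sum())

    starts = np.repeat(end5 - 1, counts)  # 0-based
    lmin, lmax = config.read_length_range
    ends = np.minimum(starts + rng.integers(lmin, lmax + 1, size=starts.size), L)
    n5 = np.zeros(L + 1, dtype=np.int64)
    np.add.at(n5, np.repeat(end5, counts), 1)
    prop = np.zeros(L + 1)
    prop[1:] = rho
    truth = HpsTruth(n5=n5, propensity=prop, n_reads=n_reads)
    return Alignments.single_reference(reference.id, starts, ends), truth


# ---------------------------------------------------------------------------
# synthetic proteome with planted KKE/D-like IDRs
# ---------------------------------------------------------------------------

def build_kke_block(rng: np.random.Generator, n_doublets: int, spacer_len: tuple[int, int] = (1, 2)) -> str:
    """Lysine-doublet block: KK doublets joined by 1-2 residue spacers drawn
    from {E, D, H, S} (E and D dominate, as in natural KKE/D repeats)."""
    spacers = np.array(list("EDHS"))
    spacer_p = np.array([0.42, 0.42, 0.08, 0.08])
    parts = ["KK"]
    for _ in range(n_doublets - 1):
        k = int(rng.integers(spacer_len[0], spacer_len[1] + 1))
        parts.append("".join(rng.choice(spacers, size=k, p=spacer_p)))
        parts.append("KK")
    return "".join(parts)


def _background_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_FREQ))


def gen_proteome(config: SimulationConfig) -> tuple[list[SeqRecord], pd.DataFrame, pd.DataFrame]:
    """Synthetic proteome with planted lysine-doublet IDRs.

    Returns ``(records, disorder_table, abundance_table)``. The first
    ``config.n_kke_proteins`` proteins carry a planted C- or N-terminal
    segment: a mixed charged lead-in followed by a KK-doublet block with
    ``config.kke_doublets`` doublets. The disorder table marks the planted
    segments (``is_kke`` truth column) plus assorted non-KKE disordered
    segments, some shorter than the 30-aa extraction cutoff. Abundances are
    lognormal (arbitrary molecules-per-cell scale).
    """
    rng = config.rng(_SALT_PROTEOME)
    records: list[SeqRecord] = []
    dis_rows = []
    for i in range(config.n_proteins):
        pid = f"SYN{i:03d}"
        length = int(np.clip(rng.lognormal(5.9, 0.35), 120, 1200))
        seq = _background_protein(rng, length)
        if i < config.n_kke_proteins:
            # lysine-enriched lead-in without KK doublets, ending in a
            # non-spacer pair so the lead never chains into the block and
            # the planted doublet count round-trips exactly
            lead = "".join("K" + str(rng.choice(list("EDSTAGN"))) for _ in range(9)) + "GA"
            block = build_kke_block(rng, config.kke_doublets)
            segment = lead + block
            if rng.random() < 0.5:  # C-terminal placement
                seq = seq[: length - len(segment)] + segment
                start = length - len(segment) + 1
            else:  # N-terminal
                seq = segment + seq[len(segment) :]
                start = 1
            dis_rows.append({"protein_id": pid, "start": start, "end": start + len(segment) - 1, "is_kke": True})
        elif rng.random() < 0.6:
            # plain disordered segment (coordinates only; content is background)
            seg_len = int(rng.integers(18, 90))
            start = int(rng.integers(1, length - seg_len + 1))
            dis_rows.append({"protein_id": pid, "start": start, "end": start + seg_len - 1, "is_kke": False})
        records.append(SeqRecord(Seq(seq), id=pid, description="synthetic protein"))
    disorder = pd.DataFrame(dis_rows)
    abundance = pd.DataFrame(
        {
            "protein_id": [r.id for r in records],
            "abundance": rng.lognormal(np.log(3000.0), 1.2, size=len(records)),
        }
    )
    return records, disorder, abundance


# ---------------------------------------------------------------------------
# qPCR / iBAQ / ROI fixtures
# ---------------------------------------------------------------------------

def gen_fixtures(
    config: SimulationConfig,
    n_ibaq: int = 60,
    missing_control_fraction: float = 0.2,
    n_cells: int = 24,
    roi_pixels: int = 40,
) -> dict[str, pd.DataFrame]:
    """Small enrichment-statistics fixtures with embedded truth columns.

    * ``qpcr``: Ct triplicates (IP and input) for rDNA regions 18S / 25S /
      NTS2 for a bait and a control construct, with the true underlying
      IP/Input ratio recorded per row.
    * ``ibaq``: two-purification (bait, control) intensity table over
      categories RP / RNAPI-associated / nucleolar / nuclear / other; a
      ``missing_control_fraction`` of control values is blanked (NaN) to
      exercise imputation; ``true_log2_enrichment`` records the planted
      effect.
    * ``roi``: per-cell intensity vectors (wide columns ``px0..``) for a
      nucleolar region, with a planted focal maximum in half of the cells,
      plus a dimmer nucleoplasm region mean.
    """
    rng = config.rng(_SALT_FIXTURES)

    qpcr_rows = []
    true_ratio = {("KKE-GFP", "18S"): 0.02, ("KKE-GFP", "25S"): 0.015, ("KKE-GFP", "NTS2"): 0.004,
                  ("GFP", "18S"): 0.002, ("GFP", "25S"): 0.002, ("GFP", "NTS2"): 0.002}
    dilution = 1.0 / 500.0
    for (construct, region), ratio in true_ratio.items():
        ct_input = rng.uniform(14.0, 18.0)
        # invert the ratio formula, then add triplicate noise
        ct_ip = ct_input + np.log2(dilution) - np.log2(ratio)
        row = {"construct": construct, "region": region, "dilution": dilution, "true_ratio": ratio}
        for k in range(3):
            row[f"ct_ip_{k + 1}"] = ct_ip + rng.normal(0, 0.12)
            row[f"ct_input_{k + 1}"] = ct_input + rng.normal(0, 0.12)
        qpcr_rows.append(row)
    qpcr = pd.DataFrame(qpcr_rows)

    categories = np.array(["RP", "RNAPI-associated", "nucleolar", "nuclear", "other"])
    cat_p = np.array([0.25, 0.10, 0.20, 0.25, 0.20])
    cat_effect = {"RP": 0.5, "RNAPI-associated": 3.0, "nucleolar": 2.0, "nuclear": 0.0, "other": -0.5}
    cats = rng.choice(categories, size=n_ibaq, p=cat_p)
    base = rng.lognormal(np.log(1e6), 1.5, size=n_ibaq)
    enrich = np.array([cat_effect[c] for c in cats]) + rng.normal(0, 0.4, size=n_ibaq)
    control = base
    bait = base * 2.0 ** enrich
    missing = rng.random(n_ibaq) < missing_control_fraction
    ibaq = pd.DataFrame(
        {
            "protein_id": [f"P{i:03d}" for i in range(n_ibaq)],
            "category": cats,
            "ibaq_bait": bait,
            "ibaq_control": np.where(missing, np.nan, control),
            "true_log2_enrichment": enrich,
        }
    )

    roi_rows = []
    for cell in range(n_cells):
        focal = cell < n_cells // 2
        base_int = rng.uniform(80, 120)
        px = rng.normal(base_int, 5.0, size=roi_pixels).clip(min=1.0)
        if focal:
            px[int(rng.integers(roi_pixels))] = base_int * rng.uniform(2.5, 4.0)
        row = {"cell_id": f"c{cell:02d}", "focal": focal, "nucleoplasm_mean": base_int * rng.uniform(0.2, 0.4)}
        row.update({f"px{j}": px[j] for j in range(roi_pixels)})
        roi_rows.append(row)
    roi = pd.DataFrame(roi_rows)

    return {"qpcr": qpcr, "ibaq": ibaq, "roi": roi}
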