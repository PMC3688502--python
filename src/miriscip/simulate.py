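"""Synthetic miRISC-IP study generator.

Emulates the three data layers of an AGO/GW182 co-immunoprecipitation
study in *C. elegans*:

* paired IP/Total small-RNA sequencing libraries (negative-binomial read
  counts around log-uniform baseline abundances, with planted
  enriched/depleted miRNAs),
* probe-level two-channel microarray signals over two platforms
  (log-normal intensities, multiple probes per gene on the main
  platform, one probe per gene on the second platform, per-probe
  detection dropout, planted IP-enriched target genes),
* 3'UTR sequences with planted 7-mer seed sites concentrated in the
  target genes.

All randomness flows from the single integer seed in
:class:`SimulationConfig`; each generator draws from its own fixed
substream of that seed, so the three layers are individually and jointly
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MiRNACountTable, ProbeSignalTable, SequenceRecord
from .seeds import seed_site

logger = logging.getLogger(__name__)

# fixed substream keys: one per generator stage
_STREAMS = {"mirna_counts": 11, "microarray": 23, "utrs": 37, "mirna_seqs": 53}

PLATFORM_MAIN = "P1"
PLATFORM_EXTRA = "P2"


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stage]]))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the design of the emulated experiments: four paired
    IP/Total small-RNA replicates, four same-platform array replicates
    plus one replicate from a second platform with a single probe per
    gene, ~250 miRNAs, and short (median ~150 nt) 3'UTRs.
    """

    seed: int = 0
    # small-RNA layer
    n_mirnas: int = 250
    n_replicates: int = 4
    frac_enriched: float = 0.06
    frac_depleted: float = 0.12
    effect_log2: float = 2.0
    dispersion: float = 0.1
    library_depth: int = 2_000_000
    # microarray layer
    n_genes: int = 3000
    frac_target_genes: float = 0.05
    probes_per_gene: tuple[int, int] = (1, 2)
    detect_dropout: float = 0.05
    n_platform2: int = 1
    signal_mu_log2: float = 8.0
    signal_sigma_log2: float = 1.5
    probe_affinity_sigma_log2: float = 0.5
    noise_sigma_log2: float = 0.3
    ratio_noise_sigma_log2: float = 0.25
    # UTR layer
    utr_len_lognorm: tuple[float, float] = (5.0, 0.6)
    planted_sites_per_target: int = 2

    def __post_init__(self) -> None:
        for name in ("frac_enriched", "frac_depleted", "frac_target_genes",
                     "detect_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_enriched + self.frac_depleted > 1.0:
            raise ValueError("frac_enriched + frac_depleted exceeds 1")
        for name in ("n_mirnas", "n_replicates", "n_genes", "library_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("probes_per_gene must be an increasing range >= 1")
        if self.planted_sites_per_target < 0:
            raise ValueError("planted_sites_per_target must be >= 0")

    def asdict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted-effect labels for recovery tests."""

    enriched_mirnas: set[str] = field(default_factory=set)
    depleted_mirnas: set[str] = field(default_factory=set)
    target_genes: set[str] = field(default_factory=set)
    planted_sites: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.enriched_mirnas & self.depleted_mirnas:
            raise ValueError("enriched and depleted miRNA sets overlap")

    def mirna_labels(self) -> pd.DataFrame:
        rows = [
            {"mirna": m, "label": "enriched"} for m in sorted(self.enriched_mirnas)
        ] + [
            {"mirna": m, "label": "depleted"} for m in sorted(self.depleted_mirnas)
        ]
        return pd.DataFrame(rows, columns=["mirna", "label"])

    def gene_labels(self) -> pd.DataFrame:
        rows = [{"gene": g, "label": "target"} for g in sorted(self.target_genes)]
        return pd.DataFrame(rows, columns=["gene", "label"])


def mirna_ids(n: int) -> list[str]:
    return [f"mir-{i + 1:04d}" for i in range(n)]


def gene_ids(n: int) -> list[str]:
    return [f"g{i + 1:05d}" for i in range(n)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float
               ) -> np.ndarray:
    """Negative-binomial draws with var = m + dispersion * m^2 (Gamma–Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def gen_mirna_counts(config: SimulationConfig) -> tuple[MiRNACountTable, GroundTruth]:
    """Simulate paired IP/Total small-RNA libraries with planted effects.

    Baseline abundances are log-uniform across four orders of magnitude.
    Total-fraction counts are negative-binomial around the baseline;
    IP-fraction means are multiplied by ``2**effect_log2`` for enriched
    and ``2**-effect_log2`` for depleted miRNAs, then renormalized so
    every library's expected depth stays within 2x of every other
    (enrichment is a composition shift, not a depth shift).
    """
    rng = _rng(config.seed, "mirna_counts")
    names = mirna_ids(config.n_mirnas)

    baseline = 10.0 ** rng.uniform(0.0, 4.0, size=config.n_mirnas)
    prop_total = baseline / baseline.sum()

    n_enr = int(round(config.frac_enriched * config.n_mirnas))
    n_dep = int(round(config.frac_depleted * config.n_mirnas))
    affected = rng.choice(config.n_mirnas, size=n_enr + n_dep, replace=False)
    enr_idx, dep_idx = affected[:n_enr], affected[n_enr:]

    fold = np.ones(config.n_mirnas)
    fold[enr_idx] = 2.0 ** config.effect_log2
    fold[dep_idx] = 2.0 ** -config.effect_log2
    prop_ip = prop_total * fold
    prop_ip = prop_ip / prop_ip.sum()

    data = {}
    for r in range(1, config.n_replicates + 1):
        # library depths jitter within [0.75, 1.35]x nominal: < 2x apart
        for frac, prop in (("IP", prop_ip), ("TOTAL", prop_total)):
            depth = config.library_depth * rng.uniform(0.75, 1.35)
            data[f"{frac}_{r}"] = _nb_counts(rng, prop * depth, config.dispersion)
    counts = pd.DataFrame(data, index=pd.Index(names, name="mirna"))
    truth = GroundTruth(
        enriched_mirnas={names[i] for i in enr_idx},
        depleted_mirnas={names[i] for i in dep_idx},
    )
    return MiRNACountTable(counts), truth


def gen_microarray(config: SimulationConfig) -> tuple[ProbeSignalTable, GroundTruth]:
    """Simulate two-platform IP/Total microarray signals with planted targets.

    Total signals are log-normal per probe (gene baseline x probe
    affinity x replicate noise); IP signals equal the Total signal times
    the gene's planted IP effect times per-measurement ratio noise.  The
    main platform carries 1–2 probes per gene over ``n_replicates``
    replicates; the extra platform has exactly one probe per gene and
    ``n_platform2`` replicates.  Each probe x replicate x channel
    detection flag is False with probability ``detect_dropout``.
    """
    rng = _rng(config.seed, "microarray")
    genes = gene_ids(config.n_genes)

    n_targets = int(round(config.frac_target_genes * config.n_genes))
    target_idx = rng.choice(config.n_genes, size=n_targets, replace=False)
    gene_effect = np.zeros(config.n_genes)
    gene_effect[target_idx] = config.effect_log2

    base = rng.normal(config.signal_mu_log2, config.signal_sigma_log2,
                      size=config.n_genes)

    lo, hi = config.probes_per_gene
    n_probes = rng.integers(lo, hi + 1, size=config.n_genes)

    rows = []
    probe_gene_idx = []
    for gi, gene in enumerate(genes):
        for p in range(n_probes[gi]):
            rows.append((f"{gene}_p{p + 1}", f"{gene}t1", gene, PLATFORM_MAIN))
            probe_gene_idx.append(gi)
        rows.append((f"{gene}_x1", f"{gene}t1", gene, PLATFORM_EXTRA))
        probe_gene_idx.append(gi)
    probe_gene_idx = np.asarray(probe_gene_idx)
    df = pd.DataFrame(rows, columns=["probe", "transcript", "gene", "platform"])
    df = df.set_index("probe")
    is_main = (df["platform"] == PLATFORM_MAIN).to_numpy()

    affinity = rng.normal(0.0, config.probe_affinity_sigma_log2, size=len(df))
    probe_base = base[probe_gene_idx] + affinity
    probe_effect = gene_effect[probe_gene_idx]

    main_reps = list(range(1, config.n_replicates + 1))
    extra_reps = list(range(config.n_replicates + 1,
                            config.n_replicates + config.n_platform2 + 1))
    for r in main_reps + extra_reps:
        on_platform = is_main if r in main_reps else ~is_main
        eps = rng.normal(0.0, config.noise_sigma_log2, size=len(df))
        eta = rng.normal(0.0, config.ratio_noise_sigma_log2, size=len(df))
        total = 2.0 ** (probe_base + eps)
        ip = total * 2.0 ** (probe_effect + eta)
        det_ip = rng.random(len(df)) >= config.detect_dropout
        det_total = rng.random(len(df)) >= config.detect_dropout
        df[f"IP_{r}"] = np.where(on_platform, ip, np.nan)
        df[f"TOTAL_{r}"] = np.where(on_platform, total, np.nan)
        df[f"DETECT_IP_{r}"] = det_ip & on_platform
        df[f"DETECT_TOTAL_{r}"] = det_total & on_platform

    truth = GroundTruth(target_genes={genes[i] for i in target_idx})
    return ProbeSignalTable(df), truth


def gen_utrs(
    config: SimulationConfig,
    mirnas: Sequence[SequenceRecord],
    truth: GroundTruth,
) -> list[SequenceRecord]:
    """Simulate 3'UTRs with seed sites planted in the target genes.

    Lengths are log-normal; background composition is uniform over ACGT.
    Each target gene's UTR receives ``planted_sites_per_target``
    non-overlapping perfect 7-mer sites (reverse complement of
    nucleotides 2–8 of a randomly chosen input miRNA); background UTRs
    are untouched, so any site they contain occurs by chance.  Planted
    positions are recorded in ``truth.planted_sites``.
    """
    if not mirnas:
        raise ValueError("gen_utrs requires at least one miRNA")
    rng = _rng(config.seed, "utrs")
    genes = gene_ids(config.n_genes)
    mu, sigma = config.utr_len_lognorm
    sites = [seed_site(m).site for m in mirnas]
    k = config.planted_sites_per_target
    min_len = max(20, 8 * k)

    records: list[SequenceRecord] = []
    failures = 0
    for gene in genes:
        is_target = gene in truth.target_genes and k > 0
        length = 0
        attempts = 0
        while length < min_len:
            length = int(round(rng.lognormal(mu, sigma)))
            attempts += 1
            if attempts > 100:
                failures += 1
                length = min_len
                break
        seq = rng.integers(0, 4, size=length)
        seq = np.frombuffer(b"ACGT", dtype=np.uint8)[seq]
        if is_target:
            positions = _nonoverlapping_positions(rng, length, k, width=7)
            for pos in positions:
                chosen = sites[rng.integers(len(sites))]
                seq[pos:pos + 7] = np.frombuffer(chosen.encode(), dtype=np.uint8)
            truth.planted_sites[gene] = sorted(positions)
        records.append(
            SequenceRecord(id=f"{gene}t1|{gene}", seq=seq.tobytes().decode())
        )
    if failures:
        logger.warning("UTR length redraw failed %d time(s); used minimum length",
                       failures)
    return records


def _nonoverlapping_positions(
    rng: np.random.Generator, length: int, k: int, width: int
) -> list[int]:
    """Draw k start positions whose [p, p+width) windows do not overlap."""
    positions: list[int] = []
    attempts = 0
    while len(positions) < k:
        pos = int(rng.integers(0, length - width + 1))
        if all(abs(pos - q) >= width for q in positions):
            positions.append(pos)
        attempts += 1
        if attempts > 1000:  # cannot happen for lengths >= 8k enforced above
            raise RuntimeError("unable to place non-overlapping sites")
    return positions


def gen_mirna_fasta(config: SimulationConfig) -> list[SequenceRecord]:
    """Random 22-nt mature miRNA sequences, one per simulated miRNA."""
    rng = _rng(config.seed, "mirna_seqs")
    names = mirna_ids(config.n_mirnas)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    for name in names:
        seq = alphabet[rng.integers(0, 4, size=22)].tobytes().decode()
        records.append(SequenceRecord(id=name, seq=seq))
    return records
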