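"""miRISC-associated mRNA identification from IP/Total microarray signal.

Within each replicate, the IP/Total signal ratio of every probe that is
reliably detected (both channels) in that replicate is converted to a
percent rank in (0, 1) — rank ``r`` (average ranks for ties) mapped to
``(r - 0.5) / n`` — so each replicate column has mean exactly 0.5 over
its own testable probes.  Probes detected in at least ``min_reliable``
replicates are *testable*; each testable probe's ranks are compared to
the pooled ranks of all testable probes by a one-tailed Welch t-test
(alternative: probe mean rank > background).  Multiple probes per gene
(and alternative transcripts) are collapsed by keeping the minimum-p
probe, then single-probe-per-gene ranks from a second array platform
are appended as an extra replicate and significance recomputed.  Genes
with ``p < alpha`` (default 0.001, strict) are called miRISC-associated.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet, ProbeSignalTable, read_probe_table, write_tsv

logger = logging.getLogger(__name__)


def testable_entities(flags: pd.DataFrame, min_reliable: int = 2) -> set[str]:
    """Entities reliably detected in at least ``min_reliable`` replicates.

    ``flags`` is an entity x replicate boolean frame where True means
    the entity was reliably detected (both channels) in that replicate.
    """
    if flags.shape[1] < 1:
        raise ValueError("need at least one replicate of detection flags")
    ok = flags.sum(axis=1) >= min_reliable
    return set(flags.index[ok])


def percent_rank(ratios: Sequence[float] | np.ndarray) -> np.ndarray:
    """Percent ranks of IP/Total ratios: (rank - 0.5) / n, average ties.

    Output lies strictly in (0, 1) and has mean exactly 0.5 for complete
    input; the endpoints 0 and 1 never occur, which keeps downstream
    t-statistics finite.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        raise ValueError("percent rank needs at least two values")
    if np.any(~np.isfinite(ratios)) or np.any(ratios <= 0):
        raise ValueError("ratios must be finite and positive")
    ranks = stats.rankdata(ratios, method="average")
    return (ranks - 0.5) / ratios.size


def _welch_greater(
    means: np.ndarray, variances: np.ndarray, ns: np.ndarray,
    bg_mean: float, bg_var: float, bg_n: int,
) -> np.ndarray:
    """Vectorized one-tailed Welch p (entity mean > background mean)."""
    se2 = variances / ns + bg_var / bg_n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (means - bg_mean) / np.sqrt(se2)
        df = se2 ** 2 / (
            (variances / ns) ** 2 / (ns - 1)
            + (bg_var / bg_n) ** 2 / (bg_n - 1)
        )
    p = stats.t.sf(t, df)
    # zero-variance entity vs zero-variance background at equal means
    p = np.where(se2 == 0, np.where(means > bg_mean, 0.0, 1.0), p)
    return p


def gene_pvalue(entity_ranks, background_ranks) -> float:
    """One-tailed Welch t-test of one entity's ranks vs the pooled background.

    Alternative: the entity's mean percent rank exceeds the background's
    (IP association).  NaN entries in ``entity_ranks`` (replicates where
    the entity was not detected) are ignored; at least two values are
    required.
    """
    e = np.asarray(entity_ranks, dtype=float)
    e = e[np.isfinite(e)]
    b = np.asarray(background_ranks, dtype=float)
    b = b[np.isfinite(b)]
    if e.size < 2:
        raise ValueError("entity needs >= 2 rank values")
    p = _welch_greater(
        np.array([e.mean()]), np.array([e.var(ddof=1)]), np.array([e.size]),
        b.mean(), b.var(ddof=1), b.size,
    )
    return float(p[0])


def collapse_probes(probe_records: pd.DataFrame) -> pd.DataFrame:
    """One record per gene: the minimum-p probe wins.

    ``probe_records`` carries one row per probe with columns
    ``transcript``, ``gene``, ``mean_rank``, ``p`` plus any rank
    columns.  Ties on p are broken by larger mean rank, then by
    lexicographic probe id.  Percent ranks are carried through
    unaltered.  Idempotent.
    """
    df = probe_records.copy()
    if "gene" not in df.columns and df.index.name == "gene":
        df = df.reset_index()
    if "transcript" not in df.columns and "chosen_transcript" in df.columns:
        df = df.rename(columns={"chosen_transcript": "transcript"})
    if "chosen_probe" in df.columns:
        df["_probe"] = df.pop("chosen_probe")
    else:
        df["_probe"] = df.index
    ordered = df.sort_values(
        ["gene", "p", "mean_rank", "_probe"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = ordered.groupby("gene", sort=True).head(1)
    best = best.rename(columns={"_probe": "chosen_probe",
                                "transcript": "chosen_transcript"})
    return best.set_index("gene")


def merge_platform(
    gene_records: pd.DataFrame,
    platform2_ranks: pd.Series,
    background_ranks: np.ndarray,
    rank_columns: Sequence[str],
    extra_column: str,
) -> pd.DataFrame:
    """Append second-platform ranks and recompute gene p-values.

    For genes present in both platforms the extra rank is added as a
    fifth observation and the one-tailed Welch p recomputed over all
    available ranks; genes absent from the second platform keep their
    original p.  Second-platform genes missing from the first cannot
    reach two observations and are dropped (logged).
    """
    out = gene_records.copy()
    out[extra_column] = platform2_ranks.reindex(out.index)
    orphans = platform2_ranks.index.difference(gene_records.index)
    if len(orphans):
        logger.info(
            "merge_platform: %d second-platform gene(s) absent from the main "
            "platform were dropped (single observation)", len(orphans)
        )
    all_rank_cols = list(rank_columns) + [extra_column]
    ranks = out[all_rank_cols].to_numpy(dtype=float)
    has_extra = np.isfinite(out[extra_column].to_numpy(dtype=float))
    ns = np.isfinite(ranks).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(ranks, axis=1)
        variances = np.nanvar(ranks, axis=1, ddof=1)
    bg = np.asarray(background_ranks, dtype=float)
    bg = bg[np.isfinite(bg)]
    p_new = _welch_greater(means, variances, ns, bg.mean(), bg.var(ddof=1), bg.size)
    out["mean_rank"] = means
    out["p"] = np.where(has_extra, p_new, out["p"].to_numpy())
    return out


def call_enriched(records: pd.DataFrame, alpha: float = 0.001) -> GeneSet:
    """Genes with p strictly below ``alpha``."""
    if records.empty:
        return GeneSet("mirisc_associated", frozenset())
    hits = records.index[records["p"] < alpha]
    return GeneSet("mirisc_associated", frozenset(hits))


class TargetEnrichment:
    """Percent-rank target-identification model over a probe signal table.

    Parameters
    ----------
    table
        Two-platform probe signals (:class:`~miriscip.io.ProbeSignalTable`).
    min_reliable
        Replicates (both channels detected) required for a probe to be
        testable on the main platform.  Default 2.
    platform2_in_background
        Whether second-platform ranks join the pooled background used by
        the one-tailed test (default True).
    """

    def __init__(self, table: ProbeSignalTable, min_reliable: int = 2,
                 platform2_in_background: bool = True):
        self.table = table
        self.min_reliable = int(min_reliable)
        self.platform2_in_background = bool(platform2_in_background)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "TargetEnrichment":
        return cls(read_probe_table(path), **kwargs)

    # -- internals ---------------------------------------------------------

    def _replicate_ranks(self, probes: pd.Index, replicates: Iterable[int]
                         ) -> pd.DataFrame:
        """Per-replicate percent ranks over that replicate's detected probes."""
        data = self.table.data.loc[probes]
        ranks = pd.DataFrame(np.nan, index=probes,
                             columns=[f"r{r}" for r in replicates])
        for r in replicates:
            det = (data[f"DETECT_IP_{r}"] & data[f"DETECT_TOTAL_{r}"]).to_numpy()
            ip = data[f"IP_{r}"].to_numpy(dtype=float)
            total = data[f"TOTAL_{r}"].to_numpy(dtype=float)
            det &= np.isfinite(ip) & np.isfinite(total) & (total > 0) & (ip > 0)
            if det.sum() < 2:
                logger.warning("replicate %d has <2 detected probes; skipped", r)
                continue
            ranks.loc[det, f"r{r}"] = percent_rank(ip[det] / total[det])
        return ranks

    def fit(self, alpha: float = 0.001) -> "TargetEnrichmentResults":
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        data = self.table.data
        platforms = self.table.platforms
        main = platforms[0]
        extra = platforms[1] if len(platforms) > 1 else None

        main_probes = data.index[data["platform"] == main]
        main_reps = self.table.platform_replicates(main)
        ranks = self._replicate_ranks(main_probes, main_reps)
        rank_cols = list(ranks.columns)

        detected = ranks.notna()
        testable = sorted(testable_entities(detected, self.min_reliable))
        ranks = ranks.loc[testable]
        n_testable_probes = len(testable)
        if n_testable_probes == 0:
            logger.warning("no testable probes; returning empty results")
            empty = pd.DataFrame(
                columns=["chosen_probe", "chosen_transcript", "mean_rank",
                         "p", "enriched"],
                index=pd.Index([], name="gene"),
            )
            return TargetEnrichmentResults(
                self, empty, alpha, n_testable_probes=0, n_testable_genes=0,
                background=np.array([]),
            )

        rank_matrix = ranks.to_numpy(dtype=float)
        background = rank_matrix[np.isfinite(rank_matrix)]

        # second platform: one probe per gene, ranked within its own replicate
        extra_col = None
        p2_gene_ranks = pd.Series(dtype=float)
        if extra is not None:
            extra_probes = data.index[data["platform"] == extra]
            extra_reps = self.table.platform_replicates(extra)
            if extra_reps:
                extra_col = f"r{extra_reps[0]}"
                p2 = self._replicate_ranks(extra_probes, extra_reps)[extra_col]
                p2 = p2.dropna()
                p2_gene_ranks = pd.Series(
                    p2.to_numpy(), index=data.loc[p2.index, "gene"].to_numpy()
                )
                p2_gene_ranks = p2_gene_ranks[~p2_gene_ranks.index.duplicated()]
                if self.platform2_in_background:
                    background = np.concatenate([background,
                                                 p2_gene_ranks.to_numpy()])

        bg_mean = float(background.mean())
        bg_var = float(background.var(ddof=1))
        bg_n = int(background.size)

        with np.errstate(invalid="ignore"):
            means = np.nanmean(rank_matrix, axis=1)
            variances = np.nanvar(rank_matrix, axis=1, ddof=1)
        ns = np.isfinite(rank_matrix).sum(axis=1)
        pvals = _welch_greater(means, variances, ns, bg_mean, bg_var, bg_n)

        probe_records = pd.concat(
            [data.loc[testable, ["transcript", "gene"]], ranks], axis=1
        )
        probe_records["mean_rank"] = means
        probe_records["p"] = pvals
        gene_records = collapse_probes(probe_records)
        n_testable_genes = len(gene_records)

        if extra_col is not None and not p2_gene_ranks.empty:
            gene_records = merge_platform(
                gene_records, p2_gene_ranks, background, rank_cols, extra_col
            )
            rank_cols = rank_cols + [extra_col]

        enriched_set = call_enriched(gene_records, alpha)
        gene_records["enriched"] = gene_records.index.isin(enriched_set.members)
        cols = (["chosen_probe", "chosen_transcript"] + rank_cols
                + ["mean_rank", "p", "enriched"])
        gene_records = gene_records[cols]
        return TargetEnrichmentResults(
            self, gene_records, alpha,
            n_testable_probes=n_testable_probes,
            n_testable_genes=n_testable_genes,
            background=background,
        )


class TargetEnrichmentResults:
    """Per-gene percent ranks, one-tailed p-values and enrichment calls."""

    def __init__(self, model: TargetEnrichment, genes: pd.DataFrame, alpha: float,
                 *, n_testable_probes: int, n_testable_genes: int,
                 background: np.ndarray):
        self.model = model
        self.genes = genes
        self.alpha = alpha
        self.n_testable_probes = n_testable_probes
        self.n_testable_genes = n_testable_genes
        self.background = background

    @property
    def enriched_genes(self) -> GeneSet:
        return GeneSet("mirisc_associated",
                       frozenset(self.genes.index[self.genes["enriched"]]))

    @property
    def testable_genes(self) -> GeneSet:
        return GeneSet("testable", frozenset(self.genes.index))

    @property
    def n_enriched(self) -> int:
        return int(self.genes["enriched"].sum())

    @property
    def mean_rank(self) -> float:
        """Mean percent rank over all testable genes (post-collapse)."""
        return float(self.genes["mean_rank"].mean())

    def gene_mean_ranks(self) -> pd.Series:
        return self.genes["mean_rank"]

    def summary(self) -> str:
        lines = [
            "miRISC-associated mRNA identification (percent ranks)",
            "=" * 54,
            f"testable probes (main platform): {self.n_testable_probes}",
            f"testable genes:                  {self.n_testable_genes}",
            f"mean percent rank (testable):    {self.mean_rank:.3f}",
            f"alpha (one-tailed, strict):      {self.alpha}",
            f"miRISC-associated genes:         {self.n_enriched}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        write_tsv(
            self.genes, path, index_label="gene",
            params={"stage": "target-enrich", "alpha": self.alpha,
                    "min_reliable": self.model.min_reliable},
        )
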