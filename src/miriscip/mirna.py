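"""IP-vs-Total miRNA enrichment from small-RNA read counts.

The analysis follows the classic AGO/GW182 co-IP small-RNA workflow:

1. per library, each miRNA's *relative concentration* is its read count
   divided by the library's total reads (a pseudocount keeps zeros off
   the log scale);
2. every relative concentration is normalized to the smallest relative
   concentration observed anywhere in the analysis and expressed in
   log2 (*relative abundance*), so all libraries share one scale whose
   minimum is exactly 0;
3. per miRNA, a two-sample Student's t-test (pooled variance,
   two-sided) compares the IP replicates' log2 abundances against the
   Total replicates'; miRNAs are called enriched (delta > 0) or
   depleted (delta < 0) at ``p < alpha``.

No multiple-testing correction is applied to the calls; a
Benjamini–Hochberg FDR column is emitted for information only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, MiRNACountTable, read_count_table, write_tsv


@dataclass
class RelativeAbundanceMatrix:
    """log2 relative abundances (miRNA x library), minimum exactly 0."""

    values: pd.DataFrame
    pseudocount: float
    min_ref: float  # the smallest relative concentration, used as normalizer


@dataclass
class MiRNAEnrichmentRecord:
    """Per-miRNA IP-vs-Total enrichment estimate and call."""

    mirna: str
    mean_ip: float
    mean_total: float
    delta: float
    p: float
    call: str  # enriched | depleted | neither


def relative_concentration(
    counts: Mapping[str, int] | pd.Series, pseudocount: float = 0.5
) -> pd.Series:
    """Read fraction per miRNA in one library: (count + pc) / sum(count + pc)."""
    series = pd.Series(counts, dtype=float)
    if series.empty:
        raise ValueError("library contains no miRNAs")
    shifted = series + pseudocount
    total = shifted.sum()
    if total <= 0:
        raise ValueError("library total is zero; use a positive pseudocount")
    return shifted / total


def relative_abundance(rel_conc: pd.DataFrame,
                       pseudocount: float = 0.5) -> RelativeAbundanceMatrix:
    """Normalize a fraction matrix to its global minimum and take log2.

    Every entry is divided by the single smallest entry across all
    libraries of the analysis, so the minimum maps to log2 = 0 and all
    values share one scale.
    """
    values = rel_conc.to_numpy(dtype=float)
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("relative concentrations must be positive and finite")
    min_ref = float(values.min())
    out = pd.DataFrame(
        np.log2(values / min_ref), index=rel_conc.index, columns=rel_conc.columns
    )
    return RelativeAbundanceMatrix(values=out, pseudocount=pseudocount,
                                   min_ref=min_ref)


def _pooled_t(ip: np.ndarray, total: np.ndarray, equal_var: bool) -> tuple[float, float]:
    """Two-sided two-sample t; degenerate zero-variance cases handled."""
    if ip.std(ddof=1) == 0 and total.std(ddof=1) == 0:
        if ip.mean() == total.mean():
            return 0.0, 1.0
        return np.inf if ip.mean() > total.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(ip, total, equal_var=equal_var)
    return float(t), float(p)


def enrichment_test(
    ip, total, alpha: float = 0.01, *, mirna: str = "", equal_var: bool = True
) -> MiRNAEnrichmentRecord:
    """Student's t-test of one miRNA's log2 abundances, IP vs Total.

    ``delta = mean(ip) - mean(total)`` is the log2 IP/Total fold;
    the call is ``enriched`` (delta > 0) or ``depleted`` (delta < 0)
    when ``p < alpha``, otherwise ``neither``.
    """
    ip = np.asarray(ip, dtype=float)
    total = np.asarray(total, dtype=float)
    if ip.size < 2 or total.size < 2:
        raise ValueError("enrichment test needs >= 2 replicates per fraction")
    _, p = _pooled_t(ip, total, equal_var)
    delta = float(ip.mean() - total.mean())
    call = "neither"
    if p < alpha and delta > 0:
        call = "enriched"
    elif p < alpha and delta < 0:
        call = "depleted"
    return MiRNAEnrichmentRecord(
        mirna=mirna, mean_ip=float(ip.mean()), mean_total=float(total.mean()),
        delta=delta, p=p, call=call,
    )


def fold_change(record: MiRNAEnrichmentRecord) -> float:
    """Linear IP/Total fold, ``2**delta``."""
    return float(2.0 ** record.delta)


def describe_fold(delta: float) -> str:
    """Human-readable fold, e.g. delta=-log2(19) → '19.0-fold depleted'."""
    if delta >= 0:
        return f"{2.0 ** delta:.1f}-fold enriched"
    return f"{2.0 ** -delta:.1f}-fold depleted"


class MirnaEnrichment:
    """IP-vs-Total enrichment model over a miRNA read-count table.

    Parameters
    ----------
    counts
        Paired IP/Total libraries (:class:`~miriscip.io.MiRNACountTable`).
    pseudocount
        Added to every count before the read-fraction step; keeps zero
        counts finite on the log2 scale.  Default 0.5.
    equal_var
        Pooled-variance Student's t (default) or Welch when False.
    """

    def __init__(self, counts: MiRNACountTable, pseudocount: float = 0.5,
                 equal_var: bool = True):
        self.counts = counts
        self.pseudocount = float(pseudocount)
        self.equal_var = bool(equal_var)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "MirnaEnrichment":
        return cls(read_count_table(path), **kwargs)

    def relative_abundance(self) -> RelativeAbundanceMatrix:
        rel = self.counts.counts.apply(
            lambda col: relative_concentration(col, self.pseudocount), axis=0
        )
        return relative_abundance(rel, self.pseudocount)

    def fit(self, alpha: float = 0.01) -> "MirnaEnrichmentResults":
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        abundance = self.relative_abundance()
        ip = abundance.values[self.counts.ip_columns].to_numpy()
        total = abundance.values[self.counts.total_columns].to_numpy()

        mean_ip = ip.mean(axis=1)
        mean_total = total.mean(axis=1)
        delta = mean_ip - mean_total
        t, p = stats.ttest_ind(ip, total, axis=1, equal_var=self.equal_var)
        # zero variance in both groups: p=1 when means agree, else p=0
        degenerate = ~np.isfinite(t)
        if degenerate.any():
            same = degenerate & (delta == 0)
            p = np.where(same, 1.0, p)
            p = np.where(degenerate & ~same, 0.0, p)
        bh = multipletests(p, method="fdr_bh")[1]

        call = np.where(
            (p < alpha) & (delta > 0), "enriched",
            np.where((p < alpha) & (delta < 0), "depleted", "neither"),
        )
        table = pd.DataFrame(
            {
                "mean_ip": mean_ip,
                "mean_total": mean_total,
                "delta_log2": delta,
                "fold_linear": 2.0 ** delta,
                "p": p,
                "bh_fdr": bh,
                "call": call,
            },
            index=self.counts.mirnas,
        )
        return MirnaEnrichmentResults(self, table, alpha, abundance)


class MirnaEnrichmentResults:
    """Per-miRNA enrichment estimates, p-values and calls."""

    def __init__(self, model: MirnaEnrichment, table: pd.DataFrame, alpha: float,
                 abundance: RelativeAbundanceMatrix):
        self.model = model
        self.table = table
        self.alpha = alpha
        self.abundance = abundance

    @property
    def enriched(self) -> GeneSet:
        names = self.table.index[self.table["call"] == "enriched"]
        return GeneSet("enriched_mirnas", frozenset(names))

    @property
    def depleted(self) -> GeneSet:
        names = self.table.index[self.table["call"] == "depleted"]
        return GeneSet("depleted_mirnas", frozenset(names))

    @property
    def n_enriched(self) -> int:
        return int((self.table["call"] == "enriched").sum())

    @property
    def n_depleted(self) -> int:
        return int((self.table["call"] == "depleted").sum())

    def records(self) -> list[MiRNAEnrichmentRecord]:
        return [
            MiRNAEnrichmentRecord(
                mirna=str(m), mean_ip=row.mean_ip, mean_total=row.mean_total,
                delta=row.delta_log2, p=row.p, call=row.call,
            )
            for m, row in self.table.iterrows()
        ]

    def summary(self) -> str:
        n = len(self.table)
        lines = [
            "miRNA IP-vs-Total enrichment",
            "=" * 40,
            f"miRNAs tested:        {n}",
            f"replicates per group: {self.model.counts.n_replicates}",
            f"pseudocount:          {self.model.pseudocount}",
            f"alpha (raw p):        {self.alpha}",
            f"enriched in IP:       {self.n_enriched}",
            f"depleted from IP:     {self.n_depleted}",
            "",
            "strongest calls (by p):",
        ]
        called = self.table[self.table["call"] != "neither"]
        top = called.nsmallest(10, "p")
        for m, row in top.iterrows():
            lines.append(
                f"  {m:<16} delta_log2={row.delta_log2:+6.2f} "
                f"p={row.p:.3g} {describe_fold(row.delta_log2)}"
            )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        write_tsv(
            self.table, path, index_label="mirna",
            params={"stage": "mirna-enrich", "alpha": self.alpha,
                    "pseudocount": self.model.pseudocount},
        )
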