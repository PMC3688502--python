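"""Perfect 7-mer miRNA seed-site statistics over 3'UTR sets.

A *seed site* is the UTR-strand 7-mer exactly complementary to
nucleotides 2–8 of a mature miRNA (5'→3'), i.e. the reverse complement
of the seed heptamer.  The module counts exact, overlapping occurrences
of site collections in UTR sets and summarizes them as matches per
1000 nt of UTR (seed density), the fraction of genes carrying at least
one site, and the density relative to a reference gene set.  The
reverse complement of each site serves as a sequence-composition
control.  Median UTR lengths between two sets are compared with Mood's
median test on a fixed quantile grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement
from scipy import stats

from .io import GeneSet, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedSite:
    """A miRNA's perfect 7-mer target site (UTR-strand sequence)."""

    mirna: str
    site: str

    def __post_init__(self) -> None:
        if len(self.site) != 7 or any(c not in "ACGT" for c in self.site):
            raise ValueError(f"site must be a 7-nt ACGT string, got {self.site!r}")


@dataclass
class SeedSiteReport:
    """Aggregate 7-mer site statistics for one gene set."""

    set_name: str
    n_genes: int
    total_utr_nt: int
    total_matches: int
    density_per_kb: float
    frac_with_site: float
    relative_density: float
    control_matches: int
    control_density_per_kb: float
    relative_control_density: float
    median_utr_len: float


def seed_site(mirna: SequenceRecord) -> SeedSite:
    """Perfect 7-mer site of a mature miRNA: revcomp of nucleotides 2–8.

    Positions are 1-based along the mature sequence 5'→3'; the returned
    site is the DNA 7-mer a UTR must contain for a perfect seed match.
    """
    if len(mirna.seq) < 8:
        raise ValueError(
            f"mature sequence {mirna.id!r} is shorter than 8 nt"
        )
    seed = mirna.seq[1:8]
    return SeedSite(mirna=mirna.id, site=reverse_complement(seed))


def control_site(site: SeedSite | str) -> str:
    """Reverse complement of the site string (the composition control).

    Equals the miRNA's own nucleotides 2–8 in DNA form, read 5'→3'; an
    involution: ``control_site(control_site(s)) == s``.
    """
    s = site.site if isinstance(site, SeedSite) else site
    return reverse_complement(s)


def count_matches(utr: SequenceRecord | str,
                  sites: Iterable[SeedSite | str]) -> int:
    """Exact overlapping occurrences of any site in one UTR.

    Each distinct site string is matched independently, so a position
    matching two distinct sites counts twice; occurrences of one site
    may overlap each other.  ``N`` never matches, on either side: sites
    containing N are ignored and UTR windows containing N cannot equal
    an ACGT site.
    """
    seq = utr.seq if isinstance(utr, SequenceRecord) else utr
    distinct = {s.site if isinstance(s, SeedSite) else s for s in sites}
    distinct = {s for s in distinct if "N" not in s}
    if not distinct:
        return 0
    widths = {len(s) for s in distinct}
    if widths == {7}:
        # all sites are 7-mers: a window matches at most one distinct site,
        # so the per-site scan collapses to one membership test per position
        return sum(1 for i in range(len(seq) - 6) if seq[i:i + 7] in distinct)
    total = 0
    for site in distinct:
        start = seq.find(site)
        while start != -1:
            total += 1
            start = seq.find(site, start + 1)
    return total


def utr_index(records: Sequence[SequenceRecord]) -> dict[str, SequenceRecord]:
    """Resolve one UTR per gene from ``transcript|gene`` FASTA headers.

    Headers without ``|`` are treated as bare gene ids.  Genes with
    several annotated UTRs (alternative transcripts) keep the longest.
    """
    by_gene: dict[str, SequenceRecord] = {}
    for rec in records:
        gene = rec.id.rsplit("|", 1)[1] if "|" in rec.id else rec.id
        cur = by_gene.get(gene)
        if cur is None or len(rec.seq) > len(cur.seq):
            by_gene[gene] = rec
    return by_gene


def density_report(
    genes: GeneSet,
    utrs_by_gene: Mapping[str, SequenceRecord],
    sites: Iterable[SeedSite | str],
    reference: GeneSet,
) -> SeedSiteReport:
    """Seed-site density of a gene set, relative to a reference set.

    Aggregates exact 7-mer matches and UTR lengths over the set's
    resolvable UTRs; ``relative_density`` is the set's matches-per-kb
    divided by the reference set's.  The same quantities computed with
    the reverse-complement control sites give the composition baseline.
    Genes without a UTR are excluded (logged); an empty set after
    exclusion is an error.
    """
    site_strings = {s.site if isinstance(s, SeedSite) else s for s in sites}
    control_strings = {control_site(s) for s in site_strings}

    def aggregate(gene_set: GeneSet):
        matches = control = nt = with_site = n = 0
        lengths = []
        missing = 0
        for gene in sorted(gene_set.members):
            rec = utrs_by_gene.get(gene)
            if rec is None:
                missing += 1
                continue
            m = count_matches(rec, site_strings)
            matches += m
            control += count_matches(rec, control_strings)
            nt += len(rec.seq)
            with_site += int(m > 0)
            lengths.append(len(rec.seq))
            n += 1
        if missing:
            logger.info("%s: %d gene(s) had no UTR and were excluded",
                        gene_set.name, missing)
        if n == 0:
            raise ValueError(f"gene set {gene_set.name!r} has no resolvable UTRs")
        return matches, control, nt, with_site, n, float(np.median(lengths))

    m, c, nt, ws, n, med = aggregate(genes)
    ref_m, ref_c, ref_nt, _, _, _ = aggregate(reference)

    density = 1000.0 * m / nt
    control_density = 1000.0 * c / nt
    ref_density = 1000.0 * ref_m / ref_nt
    ref_control_density = 1000.0 * ref_c / ref_nt

    rel = density / ref_density if ref_density > 0 else float("nan")
    rel_control = (control_density / ref_control_density
                   if ref_control_density > 0 else float("nan"))

    return SeedSiteReport(
        set_name=genes.name, n_genes=n, total_utr_nt=nt, total_matches=m,
        density_per_kb=density, frac_with_site=ws / n, relative_density=rel,
        control_matches=c, control_density_per_kb=control_density,
        relative_control_density=rel_control, median_utr_len=med,
    )


def quantile_points(values: Sequence[float] | np.ndarray,
                    n_points: int = 400) -> np.ndarray:
    """Order-statistic quantiles at probabilities i/n_points, i = 1..n_points.

    Uses the inverted-CDF quantile type, so subsampling a vector of
    exactly ``n_points`` values returns the sorted vector itself.
    Inputs shorter than ``n_points`` are returned sorted in full.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if values.size <= n_points:
        return np.sort(values)
    q = np.arange(1, n_points + 1) / n_points
    return np.quantile(values, q, method="inverted_cdf")


def median_utr_test(
    lengths_a: Sequence[float] | np.ndarray,
    lengths_b: Sequence[float] | np.ndarray,
    n_points: int = 400,
) -> tuple[float, float, float]:
    """Mood's median test of two length distributions on a quantile grid.

    Each vector is reduced to ``n_points`` quantiles (every
    100/n_points-th percentile); the pooled grand median splits the
    points into above vs at-or-below, and the 2x2 table is tested by a
    1-df chi-square without continuity correction.  Returns
    ``(median_a, median_b, p)``.  Degenerate tables (e.g. constant
    input) give p = 1 with a warning.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both length vectors must be non-empty")
    med_a = float(np.median(a))
    med_b = float(np.median(b))
    qa = quantile_points(a, n_points)
    qb = quantile_points(b, n_points)
    grand = np.median(np.concatenate([qa, qb]))
    table = np.array(
        [
            [(qa > grand).sum(), (qb > grand).sum()],
            [(qa <= grand).sum(), (qb <= grand).sum()],
        ],
        dtype=float,
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        warnings.warn("degenerate median-test table; returning p=1")
        return med_a, med_b, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    if not np.isfinite(p):
        warnings.warn("degenerate median-test table; returning p=1")
        p = 1.0
    return med_a, med_b, float(p)
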