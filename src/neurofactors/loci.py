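"""Genomic risk locus definition (FUMA-style four-step algorithm).

1. Independent significant SNPs: genome-wide significant SNPs (p < 5e-8)
   mutually independent at r2 < 0.6 within a 1 Mb window, selected greedily
   by ascending p-value.
2. Member SNPs: input SNPs in LD (r2 >= 0.6) with an independent
   significant SNP within the window.
3. Lead SNPs: the subset of independent significant SNPs mutually in LD at
   r2 < 0.1, again greedy by ascending p.
4. Loci: single-linkage merge of lead SNPs closer than 250 kb; borders are
   the member-SNP extremes.

P-value ties break by (chrom, bp) order.  LD comes from an LD source: a
``GenotypeMatrix`` (r2 computed on the fly) or a precomputed pairwise table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import GenotypeMatrix

__all__ = ["Locus", "LdSource", "GenotypeLd", "PrecomputedLd", "define_loci", "overlap_count"]


@dataclass
class Locus:
    chrom: int
    start_bp: int  # 1-based inclusive
    end_bp: int
    lead_snps: list = field(default_factory=list)
    independent_significant_snps: list = field(default_factory=list)
    member_snps: list = field(default_factory=list)

    def to_bed(self) -> tuple:
        """(chrom, start, end) in BED convention: 0-based, half-open."""
        return (self.chrom, self.start_bp - 1, self.end_bp)


class LdSource:
    """Pairwise r^2 between SNP ids."""

    def r2(self, snp_a: str, snp_b: str) -> float:  # pragma: no cover
        raise NotImplementedError


class GenotypeLd(LdSource):
    """r^2 computed on the fly from a genotype matrix."""

    def __init__(self, genotypes: GenotypeMatrix):
        self._idx = {s: j for j, s in enumerate(genotypes.snp_ids)}
        self._geno = genotypes
        self._cache: dict = {}

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        key = (snp_a, snp_b) if snp_a < snp_b else (snp_b, snp_a)
        val = self._cache.get(key)
        if val is None:
            ja, jb = self._idx[snp_a], self._idx[snp_b]
            ga = self._geno.dosages[:, ja].astype(float)
            gb = self._geno.dosages[:, jb].astype(float)
            sa, sb = ga.std(), gb.std()
            if sa == 0 or sb == 0:
                val = 0.0
            else:
                val = float(np.mean((ga - ga.mean()) * (gb - gb.mean())) / (sa * sb)) ** 2
            self._cache[key] = val
        return val


class PrecomputedLd(LdSource):
    """r^2 from a {(snp_a, snp_b): r2} mapping (symmetric; missing = error)."""

    def __init__(self, pairs: dict):
        self._pairs = dict(pairs)

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        for key in ((snp_a, snp_b), (snp_b, snp_a)):
            if key in self._pairs:
                return float(self._pairs[key])
        raise KeyError(f"no LD value for SNP pair ({snp_a}, {snp_b})")


def define_loci(
    sumstats,
    ld: LdSource,
    p_gw: float = 5e-8,
    r2_indep: float = 0.6,
    r2_lead: float = 0.1,
    window_kb: float = 1000.0,
    merge_kb: float = 250.0,
) -> list:
    """Run the four locus-definition steps on sorted summary statistics."""
    table = getattr(sumstats, "table", sumstats)
    chrom = np.asarray(table["CHR"])
    bp = np.asarray(table["BP"])
    snp = np.asarray(table["SNP"])
    p = np.asarray(table["P"], dtype=float)
    order_key = np.lexsort((bp, chrom))
    if not np.array_equal(order_key, np.arange(len(table))):
        raise ValueError("summary statistics must be sorted by (CHR, BP)")
    window_bp = window_kb * 1000.0
    merge_bp = merge_kb * 1000.0

    sig = np.nonzero(p < p_gw)[0]
    if sig.size == 0:
        return []
    # ascending p, ties by (chrom, bp)
    sig = sig[np.lexsort((bp[sig], chrom[sig], p[sig]))]

    # step 1: greedy suppression at r2 >= r2_indep within the window
    independent: list[int] = []
    for i in sig:
        if all(
            not _near(chrom, bp, i, j, window_bp) or ld.r2(snp[i], snp[j]) < r2_indep
            for j in independent
        ):
            independent.append(i)

    # step 2: member SNPs in LD r2 >= r2_indep with an independent SNP
    members: dict[int, list[int]] = {i: [i] for i in independent}
    for j in range(len(table)):
        for i in independent:
            if j != i and _near(chrom, bp, i, j, window_bp) and ld.r2(snp[i], snp[j]) >= r2_indep:
                members[i].append(j)

    # step 3: lead SNPs among independents at r2 < r2_lead
    leads: list[int] = []
    for i in independent:  # already in ascending-p order
        if all(
            not _near(chrom, bp, i, j, window_bp) or ld.r2(snp[i], snp[j]) < r2_lead
            for j in leads
        ):
            leads.append(i)

    # step 4: single-linkage merge of lead SNPs closer than merge_kb
    lead_sorted = sorted(leads, key=lambda i: (chrom[i], bp[i]))
    clusters: list[list[int]] = []
    for i in lead_sorted:
        if (
            clusters
            and chrom[clusters[-1][-1]] == chrom[i]
            and bp[i] - bp[clusters[-1][-1]] < merge_bp
        ):
            clusters[-1].append(i)
        else:
            clusters.append([i])

    # assign each independent SNP to the cluster of the nearest lead SNP
    # it tags (every lead is independent; non-lead independents are in LD
    # r2 >= r2_lead with some lead by construction of step 3)
    loci = []
    for cluster in clusters:
        cluster_leads = set(cluster)
        indep_here = []
        for i in independent:
            if i in cluster_leads:
                indep_here.append(i)
                continue
            linked = [
                j
                for j in leads
                if _near(chrom, bp, i, j, window_bp) and ld.r2(snp[i], snp[j]) >= r2_lead
            ]
            if linked:
                best = min(linked, key=lambda j: (p[j], chrom[j], bp[j]))
                if best in cluster_leads:
                    indep_here.append(i)
        member_idx = sorted({m for i in indep_here for m in members[i]})
        loci.append(
            Locus(
                chrom=int(chrom[cluster[0]]),
                start_bp=int(min(bp[m] for m in member_idx)),
                end_bp=int(max(bp[m] for m in member_idx)),
                lead_snps=[snp[i] for i in sorted(cluster, key=lambda i: bp[i])],
                independent_significant_snps=[
                    snp[i] for i in sorted(indep_here, key=lambda i: bp[i])
                ],
                member_snps=[snp[m] for m in member_idx],
            )
        )
    # merging can make member intervals of adjacent clusters overlap; merge them
    loci = _merge_overlapping(loci)
    return loci


def _near(chrom, bp, i, j, window_bp) -> bool:
    return chrom[i] == chrom[j] and abs(float(bp[i]) - float(bp[j])) <= window_bp


def _merge_overlapping(loci: list) -> list:
    out: list[Locus] = []
    for loc in sorted(loci, key=lambda l: (l.chrom, l.start_bp)):
        if out and out[-1].chrom == loc.chrom and loc.start_bp <= out[-1].end_bp:
            prev = out[-1]
            prev.end_bp = max(prev.end_bp, loc.end_bp)
            prev.lead_snps = sorted(set(prev.lead_snps) | set(loc.lead_snps))
            prev.independent_significant_snps = sorted(
                set(prev.independent_significant_snps)
                | set(loc.independent_significant_snps)
            )
            prev.member_snps = sorted(set(prev.member_snps) | set(loc.member_snps))
        else:
            out.append(loc)
    return out


def overlap_count(loci_a: list, loci_b: list):
    """Number of loci in A sharing >= 1 bp with any locus in B (plus pairs)."""
    import bisect

    by_chrom: dict[int, list] = {}
    for ib, lb in enumerate(loci_b):
        by_chrom.setdefault(lb.chrom, []).append((lb.start_bp, lb.end_bp, ib))
    for v in by_chrom.values():
        v.sort()
    count = 0
    pairs = []
    for ia, la in enumerate(loci_a):
        cands = by_chrom.get(la.chrom, [])
        # candidates starting at or before la.end_bp
        hi = bisect.bisect_right(cands, (la.end_bp, np.inf, np.inf))
        hits = [ib for start, end, ib in cands[:hi] if end >= la.start_bp]
        if hits:
            count += 1
            pairs.extend((ia, ib) for ib in sorted(hits))
    return count, pairs
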