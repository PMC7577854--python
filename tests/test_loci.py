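import numpy as np
import pandas as pd
import pytest

from neurofactors import loci as lc

from _oracles import define_loci_bruteforce, overlap_count_quadratic


def make_table(rows):
    """rows: (snp, chrom, bp, p)"""
    return pd.DataFrame(
        [
            {"SNP": s, "CHR": c, "BP": b, "A1": "A", "A2": "G", "FREQ": 0.3,
             "BETA": 0.0, "SE": 1.0, "Z": 0.0, "P": p, "N": 1000}
            for s, c, b, p in rows
        ]
    )


def ld_from_pairs(snps, pairs):
    """Symmetric LD source; unlisted pairs are r2 = 0."""
    full = {}
    for i in snps:
        for j in snps:
            if i < j:
                full[(i, j)] = 0.0
    full.update(pairs)
    return lc.PrecomputedLd(full)


class TestDefineLoci:
    def test_no_significant_snps(self):
        t = make_table([("a", 1, 100_000, 1e-4), ("b", 1, 200_000, 0.5)])
        out = lc.define_loci(t, ld_from_pairs(["a", "b"], {}))
        assert out == []

    def test_single_isolated_hit(self):
        t = make_table([("a", 1, 100_000, 1e-9), ("b", 1, 200_000, 0.5)])
        out = lc.define_loci(t, ld_from_pairs(["a", "b"], {}))
        assert len(out) == 1
        loc = out[0]
        assert loc.lead_snps == ["a"]
        assert loc.independent_significant_snps == ["a"]
        assert loc.start_bp == loc.end_bp == 100_000

    def test_suppression_and_membership(self):
        # two significant SNPs in strong LD 100 kb apart -> one independent
        # SNP, the other becomes a member extending the border; a third
        # weak-LD SNP 400 kb away forms its own locus (no merge at >= 250 kb)
        rows = [
            ("s1", 1, 100_000, 1e-12),
            ("s2", 1, 200_000, 1e-9),
            ("s3", 1, 500_000, 1e-8 / 2),
            ("s4", 1, 600_000, 0.2),
        ]
        pairs = {("s1", "s2"): 0.8, ("s2", "s3"): 0.05, ("s1", "s3"): 0.05}
        t = make_table(rows)
        ld = ld_from_pairs([r[0] for r in rows], pairs)
        out = lc.define_loci(t, ld)
        oracle = define_loci_bruteforce(t, ld.r2)
        assert len(out) == len(oracle) == 2
        loc, orc = out[0], oracle[0]
        assert loc.independent_significant_snps == orc["indep"] == ["s1"]
        assert loc.lead_snps == orc["leads"] == ["s1"]
        assert loc.member_snps == orc["members"] == ["s1", "s2"]
        assert (loc.start_bp, loc.end_bp) == (orc["start"], orc["end"]) == (100_000, 200_000)
        assert out[1].lead_snps == ["s3"]
        assert (out[1].start_bp, out[1].end_bp) == (500_000, 500_000)

    def test_no_merge_beyond_250kb(self):
        rows = [("a", 1, 100_000, 1e-9), ("b", 1, 400_000, 1e-9)]
        t = make_table(rows)
        out = lc.define_loci(t, ld_from_pairs(["a", "b"], {}))
        assert len(out) == 2

    def test_merge_below_250kb(self):
        rows = [("a", 1, 100_000, 1e-9), ("b", 1, 300_000, 1e-9)]
        t = make_table(rows)
        out = lc.define_loci(t, ld_from_pairs(["a", "b"], {}))
        assert len(out) == 1
        assert sorted(out[0].lead_snps) == ["a", "b"]

    def test_lead_selection_at_r2_lead(self):
        # second independent SNP in moderate LD (0.3) with the first: it is
        # independent (r2 < 0.6) but not a lead (r2 >= 0.1)
        rows = [("a", 1, 100_000, 1e-12), ("b", 1, 150_000, 1e-9)]
        pairs = {("a", "b"): 0.3}
        t = make_table(rows)
        out = lc.define_loci(t, ld_from_pairs(["a", "b"], pairs))
        assert len(out) == 1
        assert out[0].lead_snps == ["a"]
        assert out[0].independent_significant_snps == ["a", "b"]

    def test_window_limits_ld_checks(self):
        # strong LD but 2 Mb apart: outside the 1 Mb window, so both stay
        rows = [("a", 1, 1_000_000, 1e-12), ("b", 1, 3_000_000, 1e-9)]
        pairs = {("a", "b"): 0.9}
        t = make_table(rows)
        out = lc.define_loci(t, ld_from_pairs(["a", "b"], pairs))
        assert len(out) == 2

    def test_unsorted_input_rejected(self):
        t = make_table([("a", 1, 200_000, 1e-9), ("b", 1, 100_000, 1e-9)])
        with pytest.raises(ValueError, match="sorted"):
            lc.define_loci(t, ld_from_pairs(["a", "b"], {}))

    def test_missing_ld_pair_named(self):
        t = make_table([("a", 1, 100_000, 1e-9), ("b", 1, 150_000, 1e-9)])
        with pytest.raises(KeyError, match="a.*b|b.*a"):
            lc.define_loci(t, lc.PrecomputedLd({}))


def random_instance(rng):
    m = rng.integers(2, 10)
    chrom = rng.integers(1, 3, m)
    bp = np.sort(rng.integers(1, 2_000_000, m))
    # ensure unique positions
    bp = bp + np.arange(m)
    snps = [f"v{i}" for i in range(m)]
    order = np.lexsort((bp, chrom))
    rows = [(snps[i], int(chrom[o]), int(bp[o]), float(10 ** -rng.uniform(2, 12)))
            for i, o in enumerate(order)]
    pairs = {}
    for i in range(m):
        for j in range(i + 1, m):
            pairs[(f"v{i}", f"v{j}")] = float(rng.choice([0.0, 0.05, 0.3, 0.7, 0.9]))
    return make_table(rows), lc.PrecomputedLd(pairs)


class TestAgainstBruteForce:
    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(4242)
        for _ in range(100):
            t, ld = random_instance(rng)
            got = lc.define_loci(t, ld)
            exp = define_loci_bruteforce(t, ld.r2)
            assert len(got) == len(exp)
            for g, e in zip(got, exp):
                assert g.chrom == e["chrom"]
                assert (g.start_bp, g.end_bp) == (e["start"], e["end"])
                assert sorted(g.lead_snps) == e["leads"]
                assert sorted(g.independent_significant_snps) == e["indep"]
                assert sorted(g.member_snps) == e["members"]

    def test_threshold_monotonicity_of_snp_hierarchies(self):
        # stricter significance shrinks the independent and lead SNP sets
        # (the locus count itself is not monotone: removing a bridging lead
        # SNP can split a merged locus into two)
        rng = np.random.default_rng(77)
        for _ in range(50):
            t, ld = random_instance(rng)
            loose = lc.define_loci(t, ld, p_gw=5e-4)
            strict = lc.define_loci(t, ld, p_gw=5e-10)
            loose_i = {s for l in loose for s in l.independent_significant_snps}
            strict_i = {s for l in strict for s in l.independent_significant_snps}
            assert strict_i <= loose_i
            loose_l = {s for l in loose for s in l.lead_snps}
            strict_l = {s for l in strict for s in l.lead_snps}
            assert strict_l <= loose_l

    def test_idempotence_on_member_snps(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            t, ld = random_instance(rng)
            out = lc.define_loci(t, ld)
            if not out:
                continue
            keep = sorted({s for l in out for s in l.member_snps})
            t2 = t[t["SNP"].isin(keep)].reset_index(drop=True)
            out2 = lc.define_loci(t2, ld)
            assert [(l.chrom, l.start_bp, l.end_bp) for l in out] == [
                (l.chrom, l.start_bp, l.end_bp) for l in out2
            ]


class TestOverlap:
    def _loci(self, triples):
        return [lc.Locus(chrom=c, start_bp=s, end_bp=e) for c, s, e in triples]

    def test_identical_lists(self):
        a = self._loci([(1, 100, 200), (2, 50, 80)])
        n, pairs = lc.overlap_count(a, a)
        assert n == 2

    def test_disjoint_chromosomes(self):
        a = self._loci([(1, 100, 200)])
        b = self._loci([(2, 100, 200)])
        assert lc.overlap_count(a, b)[0] == 0

    def test_random_sets_match_quadratic_oracle(self, rng):
        for _ in range(50):
            def rand_set():
                out = []
                for _ in range(rng.integers(0, 12)):
                    c = int(rng.integers(1, 4))
                    s = int(rng.integers(1, 10_000))
                    out.append((c, s, s + int(rng.integers(1, 3_000))))
                return self._loci(out)
            A, B = rand_set(), rand_set()
            assert lc.overlap_count(A, B)[0] == overlap_count_quadratic(A, B)

    def test_bed_conversion(self):
        loc = lc.Locus(chrom=3, start_bp=1_001, end_bp=2_000)
        assert loc.to_bed() == (3, 1_000, 2_000)
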