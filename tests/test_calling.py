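"""Read filtering, strand split, CpG pileup, conversion QC, coverage,
sensitivity -- each checked against trivial contracts and naive oracles."""

import numpy as np
import pandas as pd
import pytest

import panelmeth as pm
from panelmeth import calling
from panelmeth.calling import CallingError
from panelmeth.panel import Region, cpg_positions
from panelmeth.simulate import AlignedReadPair, Mate


def _pair(read_id="p1", chrom="chr1", p1=0, s1="ACGT", p2=10, s2="ACGT",
          strand="OT", proper=True, dup=False, mapped=True):
    return AlignedReadPair(read_id, chrom, Mate(p1, s1), Mate(p2, s2), strand,
                           proper_pair=proper, duplicate=dup, mapped=mapped)


class TestPreprocess:
    def test_flag_arithmetic(self):
        pairs = [_pair(read_id=f"p{i}") for i in range(7)]
        pairs += [_pair(read_id="d1", dup=True), _pair(read_id="d2", dup=True)]
        pairs += [_pair(read_id="i1", proper=False)]
        assert len(calling.preprocess_reads(pairs)) == 7

    def test_full_overlap_counts_each_base_once(self):
        pair = _pair(p1=0, s1="ACGTACGT", p2=0, s2="ACGTACGT")
        (clipped,) = calling.preprocess_reads([pair])
        counted = len(clipped.mate1.seq) + len(clipped.mate2.seq)
        assert counted == 8  # one copy of each genomic base

    def test_partial_overlap_clipped_from_mate2(self):
        pair = _pair(p1=0, s1="AAAAA", p2=3, s2="CCCCC")
        (clipped,) = calling.preprocess_reads([pair])
        assert clipped.mate1.seq == "AAAAA"
        assert clipped.mate2.pos == 5
        assert clipped.mate2.seq == "CCC"

    def test_matches_naive_filter_on_random_fixture(self, rng):
        pairs = []
        for i in range(500):
            pairs.append(
                _pair(
                    read_id=f"p{i}",
                    p1=int(rng.integers(0, 50)),
                    p2=int(rng.integers(0, 50)),
                    proper=bool(rng.random() > 0.2),
                    dup=bool(rng.random() < 0.15),
                    mapped=bool(rng.random() > 0.05),
                )
            )
        got = {p.read_id for p in calling.preprocess_reads(pairs)}
        # independent naive re-implementation of the retention rule
        want = {
            p.read_id
            for p in pairs
            if p.mapped and p.proper_pair and not p.duplicate
        }
        assert got == want


class TestSplitByStrand:
    def test_partition_sizes(self):
        pairs = [_pair(read_id=f"t{i}", strand="OT") for i in range(6)]
        pairs += [_pair(read_id=f"b{i}", strand="OB") for i in range(4)]
        top, bottom = calling.split_by_strand(pairs)
        assert (len(top), len(bottom)) == (6, 4)
        assert {p.read_id for p in top} | {p.read_id for p in bottom} == {
            p.read_id for p in pairs
        }

    def test_empty_input(self):
        assert calling.split_by_strand([]) == ([], [])

    def test_missing_tag_raises(self):
        with pytest.raises(CallingError, match="strand"):
            calling.split_by_strand([_pair(strand="??")])

    def test_sizes_match_generator_bookkeeping(self, small_world):
        pairs = small_world["reads"]["S02"]
        top, bottom = calling.split_by_strand(pairs)
        assert len(top) == sum(1 for p in pairs if p.strand == "OT")
        assert len(top) + len(bottom) == len(pairs)


class TestCallMethylation:
    def _tiny_panel(self):
        # reference with CpGs at +2/-3 and +8/-9
        ref = {"chr1": "AACGAAAACGAAAAAA"}
        panel = pm.CapturePanel(
            regions=[Region("r1", "G1", "chr1", 0, 16, "capture")]
        )
        return ref, panel

    def test_ratio_definition(self):
        ref, panel = self._tiny_panel()
        pairs = []
        for i in range(8):
            pairs.append(_pair(read_id=f"c{i}", p1=0, s1="AACGAAAA", p2=8, s2="AACGAAAA"))
        for i in range(2):
            pairs.append(_pair(read_id=f"t{i}", p1=0, s1="AATGAAAA", p2=8, s2="AATGAAAA"))
        sites = calling.call_methylation(pairs, ref, panel, flank=0)
        site = sites[(sites["pos"] == 2) & (sites["strand"] == "+")].iloc[0]
        assert site["depth"] == 10
        assert site["ratio"] == pytest.approx(0.8)

    def test_strand_separation(self):
        """OB reads inform bottom-strand sites only (G vs A calls)."""
        ref, panel = self._tiny_panel()
        pairs = [
            _pair(read_id="b1", p1=0, s1="AACGAAAA", p2=8, s2="AACAAAAA", strand="OB")
        ]
        sites = calling.call_methylation(pairs, ref, panel, flank=0)
        plus = sites[sites["strand"] == "+"]
        minus = sites[sites["strand"] == "-"]
        assert (plus["depth"] == 0).all()  # no OT coverage
        g_site = minus[minus["pos"] == 3].iloc[0]
        a_site = minus[minus["pos"] == 9].iloc[0]
        assert (g_site["meth_count"], g_site["unmeth_count"]) == (1, 0)
        assert (a_site["meth_count"], a_site["unmeth_count"]) == (0, 1)

    def test_missing_contig_raises(self):
        _, panel = self._tiny_panel()
        with pytest.raises(CallingError, match="contig"):
            calling.call_methylation([], {"other": "ACGT"}, panel)

    def test_matches_naive_pileup_oracle(self, small_world, called_sites):
        """Vectorized caller equals a per-position brute-force pileup."""
        panel, reference = small_world["panel"], small_world["reference"]
        sample = "S03"
        filtered = calling.preprocess_reads(small_world["reads"][sample])
        target = [p for p in filtered if p.chrom != panel.lambda_contig]
        sites = called_sites[sample]

        region = panel.capture_regions[0]
        seq = reference[region.chrom]
        plus, minus = cpg_positions(seq)
        for pos in plus[(plus >= region.start) & (plus < region.end)][:6]:
            meth = unmeth = 0
            for pair in target:
                if pair.chrom != region.chrom or pair.strand != "OT":
                    continue
                for mate in pair.mates():
                    if mate.pos <= pos < mate.end:
                        base = mate.seq[pos - mate.pos]
                        meth += base == "C"
                        unmeth += base == "T"
            row = sites[
                (sites["chrom"] == region.chrom)
                & (sites["pos"] == pos)
                & (sites["strand"] == "+")
            ].iloc[0]
            assert (row["meth_count"], row["unmeth_count"]) == (meth, unmeth)


class TestConversion:
    def test_formula(self):
        assert calling.ConversionReport(C=3, T=997).efficiency_pct == pytest.approx(99.7)
        assert calling.ConversionReport(C=0, T=500).efficiency_pct == 100.0

    def test_zero_lambda_coverage_raises(self):
        with pytest.raises(CallingError, match="lambda"):
            calling.conversion_efficiency([], "ACGT")

    def test_simulation_recovers_spiked_efficiency(self):
        """Simulated lambda at 99.5% conversion measures within 3 SE."""
        panel, reference = pm.generate_panel(1, (1, 1), (150, 150), seed=41)
        truth = pm.generate_cohort_truth(panel, n_samples=1, seed=42)
        reads = pm.generate_reads(
            truth, panel, reference, mean_depth=5, lambda_depth=200,
            conversion_eff=0.995, seq_error=0.0, seed=43,
        )
        report = calling.conversion_efficiency(
            calling.preprocess_reads(reads["S01"]), reference["lambda"]
        )
        n = report.C + report.T
        se_pct = 100 * np.sqrt(0.995 * 0.005 / n)
        assert report.efficiency_pct == pytest.approx(99.5, abs=3 * se_pct)


class TestSensitivity:
    @pytest.mark.parametrize("depth,expected", [(189.6, 0.53), (100, 1.00), (200, 0.50)])
    def test_values(self, depth, expected):
        assert calling.sensitivity(depth) == expected

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(CallingError):
            calling.sensitivity(0)

    def test_strictly_decreasing_in_depth(self):
        depths = np.linspace(20, 400, 25)
        vals = [calling.sensitivity(d) for d in depths]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[0] > vals[-1]


class TestCoverage:
    def test_uniform_tiling_mean(self):
        panel = pm.CapturePanel(regions=[Region("r1", "G1", "chr1", 0, 100, "capture")])
        pairs = [
            _pair(read_id=f"p{i}", p1=0, s1="A" * 50, p2=50, s2="A" * 50)
            for i in range(50)
        ]
        report = calling.coverage_report(pairs, panel)
        assert report.mean_cov_capture == pytest.approx(50.0)

    def test_empty_panel_rejected(self):
        with pytest.raises(Exception):
            calling.coverage_report([], pm.CapturePanel(regions=[]))

    def test_matches_naive_depth_oracle(self, small_world):
        panel = small_world["panel"]
        pairs = small_world["reads"]["S04"]
        report = calling.coverage_report(pairs, panel)
        # brute force: per-base depth over capture bases from the filtered pairs
        filtered = calling.preprocess_reads(
            [p for p in pairs if p.chrom != panel.lambda_contig]
        )
        total = bases = 0
        for r in panel.capture_regions:
            depth = np.zeros(r.width, dtype=int)
            for pair in filtered:
                if pair.chrom != r.chrom:
                    continue
                for mate in pair.mates():
                    s, e = max(mate.pos, r.start), min(mate.end, r.end)
                    if s < e:
                        depth[s - r.start : e - r.start] += 1
            total += depth.sum()
            bases += r.width
        assert report.mean_cov_capture == pytest.approx(total / bases)


class TestInformativeCpgs:
    def test_direct_filter(self):
        sites = pd.DataFrame(
            {"depth": [5, 11, 20], "ratio": [0.0, 0.1, 0.2]}
        )
        assert calling.count_informative_cpgs(sites) == (3, 2)

    def test_all_zero_ratios(self):
        sites = pd.DataFrame({"depth": [15, 30], "ratio": [0.0, 0.0]})
        assert calling.count_informative_cpgs(sites) == (2, 0)

    def test_matches_bruteforce_on_cohort(self, called_sites):
        sites = called_sites["S05"]
        n_total, n_strict = calling.count_informative_cpgs(sites)
        assert n_total == int((sites["depth"] >= 1).sum())
        assert n_strict == sum(
            1
            for _, row in sites.iterrows()
            if row["depth"] > 10 and row["ratio"] > 0
        )


def test_depth_conservation(clean_world, called_sites):
    """Total site depth never exceeds retained aligned bases over CpG positions."""
    panel, reference = clean_world["panel"], clean_world["reference"]
    for sample, pairs in clean_world["reads"].items():
        filtered = calling.preprocess_reads(
            [p for p in pairs if p.chrom != panel.lambda_contig]
        )
        sites = calling.call_methylation(filtered, reference, panel)
        aligned_bases_at_sites = 0
        site_pos = {
            chrom: set(
                sites.loc[sites["chrom"] == chrom, "pos"]
            )
            for chrom in sites["chrom"].unique()
        }
        for pair in filtered:
            positions = site_pos.get(pair.chrom, set())
            for mate in pair.mates():
                aligned_bases_at_sites += sum(
                    1 for p in range(mate.pos, mate.end) if p in positions
                )
        assert sites["depth"].sum() <= aligned_bases_at_sites


def test_pooled_dinucleotide_ratio_is_weighted_average(called_sites):
    """Merging the two strands of one CpG dinucleotide gives exactly the
    count-weighted pooled ratio."""
    sites = called_sites["S01"]
    plus = sites[sites["strand"] == "+"].set_index(["chrom", "pos"])
    minus = sites[sites["strand"] == "-"].copy()
    minus["pos"] -= 1  # the G sits one base right of the C
    minus = minus.set_index(["chrom", "pos"])
    joined = plus.join(minus, lsuffix="_p", rsuffix="_m", how="inner")
    joined = joined[(joined["depth_p"] > 0) & (joined["depth_m"] > 0)]
    pooled = (joined["meth_count_p"] + joined["meth_count_m"]) / (
        joined["depth_p"] + joined["depth_m"]
    )
    weighted = (
        joined["ratio_p"] * joined["depth_p"] + joined["ratio_m"] * joined["depth_m"]
    ) / (joined["depth_p"] + joined["depth_m"])
    assert np.allclose(pooled, weighted)
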