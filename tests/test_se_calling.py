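"""Hockey-stick cutoff, SE flagging and SE-to-gene assignment."""

import numpy as np
import pytest

from crcpipe import (
    GeneModel,
    GenomicInterval,
    Peak,
    StitchedRegion,
    assign_genes,
    call_superenhancers,
    hockey_stick_cutoff,
)
from crcpipe.se_calling import se_associated_tfs
from .oracles import hockey_cutoff_bruteforce


def _region(rid, chrom, start, end, signal):
    return StitchedRegion(
        id=rid,
        interval=GenomicInterval(chrom, start, end),
        constituents=[Peak(interval=GenomicInterval(chrom, start, end))],
        signal=signal,
    )


def _gene(symbol, chrom, tss, strand="+"):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + 500, "+")
    else:
        iv = GenomicInterval(chrom, tss - 499, tss + 1, "-")
    return GeneModel(symbol, symbol, iv)


class TestHockeyStickCutoff:
    def test_all_equal_degenerates_to_zero_ses(self):
        x, y = hockey_stick_cutoff([1.0, 1.0, 1.0, 1.0])
        assert x == 4 and y == 1.0
        assert not np.any(np.array([1.0, 1.0, 1.0, 1.0]) > y)

    def test_quadratic_curve_matches_exhaustive_search(self):
        s = np.arange(1, 101, dtype=float) ** 2
        assert hockey_stick_cutoff(s) == hockey_cutoff_bruteforce(s)

    def test_piecewise_linear_elbow_near_breakpoint(self):
        # slopes m/2 then 2m around the overall slope m: elbow at the break
        n = 200
        flat = np.arange(100) * 1.0
        steep = flat[-1] + np.arange(1, 101) * 40.0
        s = np.concatenate([flat, steep])
        x, y = hockey_stick_cutoff(s)
        assert hockey_cutoff_bruteforce(s) == (x, y)
        assert 99 <= x <= 101  # within the breakpoint's flanking pair

    @pytest.mark.parametrize("seed", range(8))
    def test_random_curves_match_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 400))
        s = np.sort(rng.gamma(1.5, 10.0, n))
        assert hockey_stick_cutoff(s) == hockey_cutoff_bruteforce(s)

    def test_scale_equivariance(self, rng):
        s = np.sort(rng.gamma(1.0, 5.0, 300))
        x1, y1 = hockey_stick_cutoff(s)
        x2, y2 = hockey_stick_cutoff(s * 37.5)
        assert x1 == x2
        assert y2 == pytest.approx(37.5 * y1)
        assert np.array_equal(s > y1, s * 37.5 > y2)

    def test_adding_region_below_min_never_removes_ses(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 150))
            s = np.sort(
                np.concatenate([rng.gamma(1.0, 1.0, n), rng.gamma(1.0, 60.0, 4)])
            )
            _, y1 = hockey_stick_cutoff(s)
            before = set(np.round(s[s > y1], 9))
            s2 = np.sort(np.concatenate([[s[0] * 0.5], s]))
            _, y2 = hockey_stick_cutoff(s2)
            after = set(np.round(s2[s2 > y2], 9))
            assert before <= after


class TestCallSuperenhancers:
    def test_single_region_is_typical(self):
        table = call_superenhancers([_region("r1", "chr1", 0, 100, 5.0)])
        assert table.n_super == 0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            call_superenhancers([])

    def test_input_order_invariance(self, rng):
        regions = [
            _region(f"r{i}", "chr1", i * 1000, i * 1000 + 500, float(rng.gamma(1, 10)))
            for i in range(80)
        ]
        a = call_superenhancers(regions)
        shuffled = list(regions)
        rng.shuffle(shuffled)
        b = call_superenhancers(shuffled)
        assert {r.id for r in a.superenhancers} == {r.id for r in b.superenhancers}
        assert a.cutoff == b.cutoff

    def test_planted_ses_called_background_not(self, pipeline_run):
        result, truth, _ = pipeline_run
        table = result.table
        planted = set(truth.core_tfs) | set(truth.near_miss_tfs)
        super_spans = {
            (r.interval.chrom, r.interval.start, r.interval.end)
            for r in table.superenhancers
        }
        for tf in planted:
            chrom, start, end = truth.planted_se[tf]
            assert any(
                c == chrom and s <= start and end <= e for c, s, e in super_spans
            ), f"planted SE of {tf} not called super"
        # no background singleton is flagged
        for r in table.superenhancers:
            names = {c.name.split(",")[0] for c in r.constituents}
            assert not any(n.startswith(("bg_", "single_")) for n in names)


class TestAssignGenes:
    def _table(self, *regions):
        table = call_superenhancers(list(regions))
        return table

    def test_tss_inside_se_distance_zero(self):
        regions = [
            _region("low", "chr1", 0, 10, 1.0),
            _region("se", "chr1", 5000, 9000, 100.0),
            _region("low2", "chr1", 20_000, 20_010, 1.1),
        ]
        table = self._table(*regions)
        assert {r.id for r in table.superenhancers} == {"se"}
        asn = assign_genes(table, [_gene("A", "chr1", 6000)], window=50_000)
        assert asn["se"].distances["A"] == 0
        assert asn["se"].primary_gene == "A"

    def test_window_boundary_is_inclusive_only(self):
        regions = [
            _region("low", "chr1", 0, 10, 1.0),
            _region("low2", "chr1", 300_000, 300_010, 1.1),
            _region("se", "chr1", 100_000, 101_000, 100.0),
        ]
        table = self._table(*regions)
        inside = _gene("IN", "chr1", 101_000 - 1 + 1000)  # 1000 bp past end-1
        outside = _gene("OUT", "chr1", 101_000 - 1 + 1001)
        asn = assign_genes(table, [inside, outside], window=1000)
        assert asn["se"].genes == ["IN"]

    def test_restrict_to_limits_symbols(self):
        regions = [
            _region("low", "chr1", 0, 10, 1.0),
            _region("low2", "chr1", 300_000, 300_010, 1.1),
            _region("se", "chr1", 100_000, 101_000, 100.0),
        ]
        table = self._table(*regions)
        genes = [_gene("A", "chr1", 100_500), _gene("B", "chr1", 100_600)]
        asn = assign_genes(table, genes, window=1000, restrict_to=["B"])
        assert asn["se"].genes == ["B"]

    def test_matches_allpairs_oracle(self, rng):
        regions = [_region("low", "chr1", 0, 10, 0.01)]
        for i in range(40):
            start = int(rng.integers(0, 1_000_000))
            regions.append(
                _region(f"r{i}", "chr1", start, start + int(rng.integers(500, 5000)),
                        float(rng.gamma(1, 20)) + 50)
            )
        genes = [
            _gene(f"G{j:02d}", "chr1", int(rng.integers(0, 1_000_000)))
            for j in range(30)
        ]
        table = call_superenhancers(regions)
        window = 25_000
        asn = assign_genes(table, genes, window=window)
        for r in table.superenhancers:
            expected = sorted(
                g.symbol
                for g in genes
                if (
                    r.interval.start <= g.tss < r.interval.end
                    or min(
                        abs(g.tss - r.interval.start),
                        abs(g.tss - (r.interval.end - 1)),
                    )
                    <= window
                )
            )
            assert asn[r.id].genes == expected

    def test_core_tfs_se_associated_with_planted_primary(self, pipeline_run):
        result, truth, _ = pipeline_run
        tf_map = se_associated_tfs(result.assignments)
        region_by_id = {r.id: r for r in result.table.regions}
        for tf in truth.core_tfs:
            assert tf in tf_map, f"{tf} not SE-associated"
            chrom, start, end = truth.planted_se[tf]
            primaries = [
                result.assignments[se_id].primary_gene for se_id in tf_map[tf]
            ]
            assert tf in primaries
            hosted = [
                region_by_id[se_id]
                for se_id in tf_map[tf]
                if result.assignments[se_id].primary_gene == tf
            ]
            assert any(
                r.interval.chrom == chrom
                and r.interval.start <= start
                and end <= r.interval.end
                for r in hosted
            )
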