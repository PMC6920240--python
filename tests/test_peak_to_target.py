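"""Peak clustering, filtering, gene assignment, ranking, and primer regions."""

import itertools

import networkx as nx
import numpy as np
import pytest

from tfsigkit import (
    ConfigurationError,
    Direction,
    GeneAnnotation,
    GeneAnnotationTable,
    GeneId,
    Peak,
    PeakCluster,
    PeakSet,
    SignatureRecord,
    SignatureTable,
    ValidationError,
    assign_genes,
    filter_peaks,
    harmonize_studies,
    prioritize,
    propose_regions,
)


def _peakset(study, triples):
    return PeakSet(
        [Peak("chr1", s, e, i, study) for s, e, i in triples], study
    )


def _random_peaksets(rng, n_peaks, n_studies, span=100_000):
    sets = []
    per = n_peaks // n_studies
    for j in range(n_studies):
        peaks = []
        for _ in range(per):
            chrom = f"chr{int(rng.integers(1, 3))}"
            s = int(rng.integers(0, span))
            peaks.append(
                Peak(chrom, s, s + int(rng.integers(1, 900)),
                     float(rng.uniform(0, 50)), f"s{j}")
            )
        sets.append(PeakSet(peaks, f"s{j}"))
    return sets


def _brute_force_clusters(peaksets):
    """Connected components of the pairwise interval-overlap graph."""
    peaks = [p for ps in peaksets for p in ps.peaks]
    g = nx.Graph()
    g.add_nodes_from(range(len(peaks)))
    for i, j in itertools.combinations(range(len(peaks)), 2):
        a, b = peaks[i], peaks[j]
        if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
            g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        members = [peaks[i] for i in comp]
        out.append(
            (
                members[0].chrom,
                min(p.start for p in members),
                max(p.end for p in members),
                frozenset(p.study_id for p in members),
                max(p.intensity for p in members),
            )
        )
    return sorted(out)


class TestHarmonize:
    def test_single_study_each_peak_its_own_cluster(self):
        ps = _peakset("s1", [(0, 100, 5), (200, 300, 7)])
        clusters = harmonize_studies([ps])
        assert len(clusters) == 2
        assert all(c.studies == frozenset({"s1"}) for c in clusters)

    def test_overlapping_peaks_merge_across_studies(self):
        clusters = harmonize_studies(
            [_peakset("s1", [(100, 200, 5)]), _peakset("s2", [(150, 250, 9)])]
        )
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.end) == (100, 250)
        assert c.studies == frozenset({"s1", "s2"})
        assert c.intensity == 9

    def test_bookended_intervals_do_not_merge(self):
        clusters = harmonize_studies(
            [_peakset("s1", [(100, 200, 5)]), _peakset("s2", [(200, 300, 9)])]
        )
        assert len(clusters) == 2

    def test_matches_connected_components_oracle(self, rng):
        sets = _random_peaksets(rng, 600, 3)
        clusters = harmonize_studies(sets)
        got = sorted(
            (c.chrom, c.start, c.end, c.studies, c.intensity) for c in clusters
        )
        assert got == _brute_force_clusters(sets)

    def test_idempotent_on_cluster_envelopes(self, rng):
        sets = _random_peaksets(rng, 300, 2)
        clusters = harmonize_studies(sets)
        envelopes = PeakSet(
            [Peak(c.chrom, c.start, c.end, c.intensity, "env") for c in clusters], "env"
        )
        again = harmonize_studies([envelopes])
        assert [(c.chrom, c.start, c.end) for c in again] == [
            (c.chrom, c.start, c.end) for c in clusters
        ]

    def test_duplicate_study_id_rejected(self):
        a = _peakset("s1", [(0, 10, 1)])
        with pytest.raises(ValidationError):
            harmonize_studies([a, _peakset("s1", [(20, 30, 1)])])


def _cluster(start, end, studies, intensity, chrom="chr1"):
    members = [Peak(chrom, start, end, intensity, s) for s in studies]
    return PeakCluster(chrom, start, end, members, frozenset(studies), intensity)


class TestFilterPeaks:
    @pytest.mark.parametrize(
        "intensity,studies,kept",
        [
            (10.0, ("s1", "s2"), True),   # boundary inclusive on intensity
            (50.0, ("s1",), False),        # needs more than one study
            (9.9, ("s1", "s2", "s3"), False),
        ],
    )
    def test_boundary_semantics(self, intensity, studies, kept):
        clusters = [_cluster(0, 100, studies, intensity)]
        assert (len(filter_peaks(clusters)) == 1) is kept

    def test_antitone_in_both_thresholds(self, rng):
        clusters = [
            _cluster(i * 1000, i * 1000 + 100,
                     tuple(f"s{k}" for k in range(int(rng.integers(1, 5)))),
                     float(rng.uniform(0, 30)))
            for i in range(60)
        ]
        sizes_i = [len(filter_peaks(clusters, mi, 1)) for mi in np.linspace(0, 40, 20)]
        sizes_s = [len(filter_peaks(clusters, 0, ms)) for ms in range(1, 6)]
        assert sizes_i == sorted(sizes_i, reverse=True)
        assert sizes_s == sorted(sizes_s, reverse=True)


def _annotation(entries):
    return GeneAnnotationTable(
        [GeneAnnotation(GeneId(sym), chrom, strand, s, e)
         for sym, chrom, strand, s, e in entries]
    )


class TestAssignGenes:
    def test_tss_inside_cluster_distance_zero(self):
        ann = _annotation([("G1", "chr1", "+", 150, 2150)])
        got = assign_genes([_cluster(100, 300, ("s1", "s2"), 12)], ann)
        assert len(got) == 1 and got[0].distance == 0

    def test_window_boundary_half_open(self):
        clusters = [_cluster(5000, 5400, ("s1", "s2"), 12)]
        inside = _annotation([("G1", "chr1", "+", 15399, 17399)])
        outside = _annotation([("G2", "chr1", "+", 15400, 17400)])
        got_in = assign_genes(clusters, inside, window=10_000)
        assert [a.gene.symbol for a in got_in] == ["G1"]
        assert got_in[0].distance == 9_999
        assert assign_genes(clusters, outside, window=10_000) == []

    def test_minus_strand_tss_is_interval_end(self):
        # TSS of a minus-strand gene is end - 1
        ann = _annotation([("G1", "chr1", "-", 20_000, 25_400)])
        clusters = [_cluster(25_000, 25_600, ("s1", "s2"), 12)]
        got = assign_genes(clusters, ann, window=0)
        assert len(got) == 1 and got[0].distance == 0

    def test_matches_all_pairs_brute_force(self, rng):
        genes = []
        for i in range(200):
            s = int(rng.integers(0, 500_000))
            genes.append((f"G{i:03d}", f"chr{int(rng.integers(1, 3))}",
                          "+" if rng.random() < 0.5 else "-", s, s + int(rng.integers(100, 5000))))
        ann = _annotation(genes)
        clusters = []
        for i in range(300):
            s = int(rng.integers(0, 500_000))
            clusters.append(_cluster(s, s + int(rng.integers(50, 2000)),
                                     ("s1", "s2"), 15, chrom=f"chr{int(rng.integers(1, 3))}"))
        window = 10_000
        got = {(id(a.cluster), a.gene.symbol): a.distance
               for a in assign_genes(clusters, ann, window)}
        expected = {}
        for c in clusters:
            for rec in ann:
                if rec.chrom != c.chrom:
                    continue
                tss = rec.tss
                if c.start - window <= tss < c.end + window:
                    if c.start <= tss < c.end:
                        d = 0
                    else:
                        d = c.start - tss if tss < c.start else tss - c.end
                    expected[(id(c), rec.gene.symbol)] = d
        assert got == expected

    def test_negative_window_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_genes([], _annotation([]), window=-1)


class TestPrioritize:
    def _sig(self, syms):
        return SignatureTable(
            [SignatureRecord(GeneId(s), Direction.UP, False) for s in syms]
        )

    def test_non_signature_assignments_dropped(self, rng):
        ann = _annotation([("G1", "chr1", "+", 150, 1000)])
        assignments = assign_genes([_cluster(100, 300, ("s1", "s2"), 12)], ann)
        assert len(prioritize(assignments, self._sig(["OTHER"]))) == 0

    def test_stated_tie_break_order(self):
        ann = _annotation(
            [("GA", "chr1", "+", 150, 1000),
             ("GB", "chr1", "+", 10_150, 11_000),
             ("GC", "chr1", "+", 20_150, 21_000)]
        )
        clusters = [
            _cluster(100, 300, ("s1", "s2"), 40),
            _cluster(10_100, 10_300, ("s1", "s2", "s3"), 25),
            _cluster(20_100, 20_300, ("s1", "s2"), 25),
        ]
        table = prioritize(assign_genes(clusters, ann, window=0),
                           self._sig(["GA", "GB", "GC"]))
        assert table.gene.tolist() == ["GA", "GB", "GC"]

    def test_ordering_matches_independent_sort(self, rng):
        ann = _annotation(
            [(f"G{i:02d}", "chr1", "+", i * 20_000 + 150, i * 20_000 + 1000)
             for i in range(30)]
        )
        clusters = [
            _cluster(i * 20_000 + 100, i * 20_000 + 300,
                     tuple(f"s{k}" for k in range(int(rng.integers(2, 5)))),
                     float(rng.choice([10, 20, 20, 30])))
            for i in range(30)
        ]
        table = prioritize(assign_genes(clusters, ann, window=0),
                           self._sig([f"G{i:02d}" for i in range(30)]))
        keys = list(zip(-table.intensity, -table.n_studies, table.gene))
        assert keys == sorted(keys)


class TestProposeRegions:
    def _ann_plus(self):
        return _annotation([("G1", "chr1", "+", 50_000, 60_000)])

    def test_plus_strand_control_centered_5kb_upstream(self):
        cluster = _cluster(49_800, 50_200, ("s1", "s2"), 20)
        binding, control = propose_regions(GeneId("G1"), cluster, self._ann_plus())
        assert (binding.start, binding.end) == (49_800, 50_200)
        assert (control.start, control.end) == (44_800, 45_200)
        assert control.kind == "negative_control"

    def test_overlapping_control_is_shifted_until_disjoint(self):
        # huge cluster: the 5 kb-offset control would land inside it
        cluster = _cluster(30_000, 58_000, ("s1", "s2"), 20)
        binding, control = propose_regions(GeneId("G1"), cluster, self._ann_plus())
        assert control.end <= binding.start or control.start >= binding.end

    def test_minus_strand_control_goes_downstream_in_coordinates(self):
        ann = _annotation([("G1", "chr1", "-", 50_000, 60_000)])
        cluster = _cluster(59_800, 60_200, ("s1", "s2"), 20)
        _, control = propose_regions(GeneId("G1"), cluster, ann)
        assert control.start > 60_000  # 5' of a minus-strand gene is rightward

    def test_absent_gene_is_lookup_error(self):
        with pytest.raises(LookupError):
            propose_regions(GeneId("NOPE"), _cluster(0, 100, ("s1",), 5), self._ann_plus())

    def test_invariants_over_random_cases(self, rng):
        for _ in range(300):
            tss = int(rng.integers(10_000, 200_000))
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = (tss, tss + 2_000) if strand == "+" else (tss - 1_999, tss + 1)
            ann = _annotation([("G1", "chr1", strand, start, end)])
            cs = tss + int(rng.integers(-8_000, 8_000))
            cluster = _cluster(max(cs, 0), max(cs, 0) + int(rng.integers(100, 6_000)),
                               ("s1", "s2"), 15)
            binding, control = propose_regions(GeneId("G1"), cluster, ann)
            assert control.chrom == binding.chrom == "chr1"
            assert control.start >= 0 and control.start < control.end
            assert control.end <= binding.start or control.start >= binding.end
            assert control.end - control.start == binding.end - binding.start
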