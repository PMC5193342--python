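"""Generator behaviour: determinism, Mendelian structure, signal model."""

import numpy as np
import pytest

from triocnv import simulate as sim


class TestMarkerMap:
    def test_deterministic_and_sorted(self):
        kwargs = dict(
            n_markers=1000,
            chromosome_lengths={"chr1": 10_000_000, "chr2": 5_000_000},
            seed=7,
        )
        m1 = sim.generate_marker_map(**kwargs)
        m2 = sim.generate_marker_map(**kwargs)
        assert m1.n_markers == 1000
        assert np.array_equal(m1.position, m2.position)
        assert np.array_equal(m1.gc_fraction, m2.gc_fraction)
        for chrom in ("chr1", "chr2"):
            assert np.all(np.diff(m1.position[m1.chrom_mask(chrom)]) > 0)

    def test_cnv_probe_fraction_binomial(self):
        m = sim.generate_marker_map(
            4000, {"chr1": 50_000_000}, cnv_probe_fraction=0.1, seed=3
        )
        frac = m.is_cnv_probe.mean()
        se = np.sqrt(0.1 * 0.9 / 4000)
        assert abs(frac - 0.1) < 3 * se

    @pytest.mark.parametrize(
        "lengths", [{}, {"chr1": 0}, {"chr1": -5}], ids=["none", "zero", "negative"]
    )
    def test_degenerate_chromosomes_error(self, lengths):
        with pytest.raises(ValueError):
            sim.generate_marker_map(100, lengths, seed=0)


class TestTrios:
    def test_cohort_size_and_unique_ids(self):
        trios = sim.generate_trios(660, seed=5)
        assert len(trios) == 660
        ids = {i for t in trios for i in t.members}
        assert len(ids) == 1980

    def test_single_family(self):
        (trio,) = sim.generate_trios(1, seed=0)
        assert len(set(trio.members)) == 3
        assert trio.offspring_affected

    def test_sex_ratio(self):
        trios = sim.generate_trios(2000, sex_ratio=0.51, seed=9)
        male = np.mean([t.offspring_sex == "M" for t in trios])
        se = np.sqrt(0.51 * 0.49 / 2000)
        assert abs(male - 0.51) < 3 * se


class TestSpikeCnvs:
    LOCUS = [sim.CnvLocus("chr1", 1_000_000, 1_400_000, 1, "test")]

    def test_de_novo_rate_extremes(self):
        trios = sim.generate_trios(50, seed=1)
        inherited = sim.spike_cnvs(trios, self.LOCUS, 1.0, de_novo_rate=0.0, seed=2)
        offspring = {t.offspring_id for t in trios}
        parents_with = {e.sample_id for e in inherited if e.sample_id not in offspring}
        for e in inherited:
            if e.sample_id in offspring:
                trio = next(t for t in trios if t.offspring_id == e.sample_id)
                assert trio.father_id in parents_with or trio.mother_id in parents_with
        de_novo = sim.spike_cnvs(trios, self.LOCUS, 1.0, de_novo_rate=1.0, seed=2)
        assert all(e.sample_id in offspring for e in de_novo)
        assert all(e.origin == "de_novo" for e in de_novo)

    def test_carrier_count_matches_frequency(self):
        trios = sim.generate_trios(582, seed=4)
        events = sim.spike_cnvs(trios, self.LOCUS, 0.0155, de_novo_rate=0.0, seed=6)
        offspring = {t.offspring_id for t in trios}
        carriers = {e.sample_id for e in events} & offspring
        se = np.sqrt(582 * 0.0155 * (1 - 0.0155))
        assert abs(len(carriers) - 582 * 0.0155) < 3 * se

    def test_locus_outside_map_errors(self):
        trios = sim.generate_trios(2, seed=0)
        m = sim.generate_marker_map(100, {"chr1": 1_000_000}, seed=0)
        bad = [sim.CnvLocus("chr9", 1, 1000, 1)]
        with pytest.raises(ValueError, match="outside marker map"):
            sim.spike_cnvs(trios, bad, 0.5, seed=0, marker_map=m)


class TestEmitIntensities:
    def test_null_sample_centred(self, null_panel):
        assert abs(null_panel.lrr[0].mean()) < 3 * 0.15 / np.sqrt(2000)

    def test_null_calibration_per_marker(self, null_panel):
        # across the 60 samples each marker should be ~N(0, noise_sd^2)
        mean_of_means = null_panel.lrr.mean(axis=0).mean()
        assert abs(mean_of_means) < 3 * 0.15 / np.sqrt(60 * 2000)
        sds = null_panel.lrr.std(axis=0, ddof=1)
        assert abs(sds.mean() - 0.15) < 0.01

    def test_deletion_lowers_segment_mean(self, small_map):
        trios = sim.generate_trios(1, seed=0)
        ev = [sim.CnvEvent(trios[0].offspring_id, "chr1", 5_000_000, 7_000_000, 1, "de_novo")]
        panel = sim.emit_intensities(trios, small_map, ev, gc_lrr_coeff=0.0, seed=1)
        i = panel.sample_index(trios[0].offspring_id)
        mask = small_map.overlap_mask("chr1", 5_000_000, 7_000_000)
        assert panel.lrr[i, mask].mean() < panel.lrr[i].mean() - 0.3

    def test_duplication_baf_bands(self, small_map):
        trios = sim.generate_trios(1, seed=0)
        ev = [sim.CnvEvent(trios[0].offspring_id, "chr1", 2_000_000, 20_000_000, 3, "de_novo")]
        panel = sim.emit_intensities(trios, small_map, ev, baf_noise_sd=0.02, seed=1)
        i = panel.sample_index(trios[0].offspring_id)
        mask = small_map.overlap_mask("chr1", 2_000_000, 20_000_000)
        baf = panel.baf[i, mask]
        near_third = np.abs(baf - 1 / 3) < 0.06
        near_two_thirds = np.abs(baf - 2 / 3) < 0.06
        assert near_third.sum() >= 5 and near_two_thirds.sum() >= 5

    def test_unknown_sample_errors(self, small_map, small_trios):
        ev = [sim.CnvEvent("nobody", "chr1", 1, 1000, 1, "de_novo")]
        with pytest.raises(ValueError, match="unknown sample"):
            sim.emit_intensities(small_trios, small_map, ev, seed=0)

    def test_bitwise_determinism(self, small_map, small_trios):
        ev = sim.spike_cnvs(
            small_trios,
            [sim.CnvLocus("chr1", 1_000_000, 1_500_000, 3)],
            0.3,
            seed=5,
        )
        p1 = sim.emit_intensities(small_trios, small_map, ev, seed=42)
        p2 = sim.emit_intensities(small_trios, small_map, ev, seed=42)
        assert np.array_equal(p1.lrr, p2.lrr) and np.array_equal(p1.baf, p2.baf)

    def test_mendelian_consistency_of_inherited_events(self, small_trios):
        events = sim.spike_cnvs(
            small_trios,
            [sim.CnvLocus("chr1", 10_000_000, 10_500_000, 1)],
            0.8,
            de_novo_rate=0.0,
            seed=13,
        )
        offspring = {t.offspring_id: t for t in small_trios}
        by_sample = {}
        for e in events:
            by_sample.setdefault(e.sample_id, []).append(e)
        for e in events:
            if e.sample_id not in offspring:
                continue
            t = offspring[e.sample_id]
            parental = by_sample.get(t.father_id, []) + by_sample.get(t.mother_id, [])
            # reciprocal overlap >= 50% with a same-type parental event
            assert any(
                p.copy_number == e.copy_number
                and min(
                    (min(p.end, e.end) - max(p.start, e.start) + 1) / (p.end - p.start + 1),
                    (min(p.end, e.end) - max(p.start, e.start) + 1) / (e.end - e.start + 1),
                )
                >= 0.5
                for p in parental
            )


class TestTrioGenotypes:
    def test_mendelian_transmission(self):
        trios = sim.generate_trios(100, seed=0)
        g = sim.simulate_trio_genotypes(trios, 50, seed=1)
        assert np.all(g.offspring == g.transmitted_father + g.transmitted_mother)
        # transmitted allele is always one the parent carries
        assert np.all((g.transmitted_father <= g.father) | (g.father == -1))
        assert np.all((g.transmitted_father >= g.father - 1) | (g.father == -1))

    def test_transmission_distortion(self):
        trios = sim.generate_trios(3000, seed=2)
        g = sim.simulate_trio_genotypes(
            trios, 2, maf=0.5, risk_markers=[0], transmission_or=2.0, seed=3
        )
        het = g.father[:, 0] == 1
        rate = g.transmitted_father[het, 0].mean()
        se = np.sqrt(rate * (1 - rate) / het.sum())
        assert abs(rate - 2 / 3) < 4 * se
        het_null = g.father[:, 1] == 1
        rate_null = g.transmitted_father[het_null, 1].mean()
        assert abs(rate_null - 0.5) < 4 * np.sqrt(0.25 / het_null.sum())
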