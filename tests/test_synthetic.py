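"""Synthetic generator: determinism, planted structure, signal model."""

import filecmp

import numpy as np
import pytest

from enhancerclass.io import overlaps, read_bed, read_bedgraph, read_fasta, read_jaspar_pfm
from enhancerclass.synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_genome,
    generate_pwms,
    place_enhancers,
    simulate_tracks,
)

SMALL = dict(n_chroms=1, chrom_length=60_000, n_positives=40, n_motifs=4)


class TestGenome:
    def test_gc_zero_gives_at_genome(self):
        cfg = SyntheticConfig(seed=1, gc_content=0.0, **SMALL)
        genome, tracts = generate_genome(cfg, np.random.default_rng(1))
        assert set(genome["chr1"]) <= {"A", "T"}
        assert tracts == []

    def test_determinism(self):
        cfg = SyntheticConfig(seed=7, **SMALL)
        g1, _ = generate_genome(cfg, np.random.default_rng(7))
        g2, _ = generate_genome(cfg, np.random.default_rng(7))
        assert g1 == g2

    def test_repeat_tracts_cover_requested_fraction(self):
        cfg = SyntheticConfig(seed=2, repeat_fraction=0.05, **SMALL)
        genome, tracts = generate_genome(cfg, np.random.default_rng(2))
        assert tracts
        covered = sum(t.length for t in tracts)
        assert covered >= 0.05 * cfg.chrom_length
        # tracts really are 2-mer repeats
        for t in tracts[:3]:
            seq = genome.fetch(t)
            assert seq == (seq[:2] * (t.length // 2 + 1))[: t.length]

    def test_infeasible_config_rejected(self):
        cfg = SyntheticConfig(seed=1, n_chroms=1, chrom_length=60_000, pos_length_mean=50_000)
        with pytest.raises(ValueError, match="infeasible"):
            generate_genome(cfg, np.random.default_rng(1))


class TestPwms:
    def test_shapes_dominance_and_ids(self):
        cfg = SyntheticConfig(seed=3, **SMALL)
        pwms = generate_pwms(cfg, np.random.default_rng(3))
        assert len(pwms) == 4
        lo, hi = cfg.motif_length_range
        for pwm in pwms:
            assert lo <= pwm.length <= hi
            np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-9)
            assert (pwm.matrix.max(axis=1) >= 0.7).all()
        assert [p.id for p in pwms] == ["TF001", "TF002", "TF003", "TF004"]


class TestEnhancers:
    def test_fixed_length_and_no_overlap(self):
        cfg = SyntheticConfig(seed=4, pos_length_sd=0.0, **SMALL)
        rng = np.random.default_rng(4)
        genome, _ = generate_genome(cfg, rng)
        positives = place_enhancers(cfg, genome, rng)
        assert len(positives) == cfg.n_positives
        assert {p.length for p in positives} == {round(cfg.pos_length_mean)}
        for i, a in enumerate(positives):
            assert not any(overlaps(a, b) for b in positives[i + 1 :])

    def test_no_plants_leaves_background(self):
        cfg = SyntheticConfig(seed=5, plants_per_enhancer=0.0, **SMALL)
        rng = np.random.default_rng(5)
        genome, _ = generate_genome(cfg, rng)
        before = genome["chr1"]
        place_enhancers(cfg, genome, rng)
        assert genome["chr1"] == before


class TestTracks:
    def test_noise_free_effect_exactly_delta(self):
        cfg = SyntheticConfig(
            seed=6, noise_sd=0.0, informative_marks={"H3K4me1": 5.0}, **SMALL
        )
        rng = np.random.default_rng(6)
        genome, _ = generate_genome(cfg, rng)
        positives = place_enhancers(cfg, genome, rng)
        tracks = simulate_tracks(cfg, genome, positives, rng)
        track = next(t for t in tracks if t.mark == "H3K4me1")
        vec = track.values["chr1"]
        enhancer_windows = set()
        for p in positives:
            enhancer_windows.update(range(p.start // 50, (p.end - 1) // 50 + 1))
        for i, v in enumerate(vec):
            assert v == (5.0 if i in enhancer_windows else 0.0)
        # uninformative marks are all-zero without noise
        other = next(t for t in tracks if t.mark == "H3K4me3")
        assert not other.values["chr1"].any()

    def test_uninformative_mark_has_equal_class_means(self):
        cfg = SyntheticConfig(seed=7, noise_sd=1.0, **SMALL)
        rng = np.random.default_rng(7)
        genome, _ = generate_genome(cfg, rng)
        positives = place_enhancers(cfg, genome, rng)
        tracks = simulate_tracks(cfg, genome, positives, rng)
        track = next(t for t in tracks if t.mark == "PolII")
        vec = track.values["chr1"]
        mask = np.zeros(vec.size, dtype=bool)
        for p in positives:
            mask[p.start // 50 : (p.end - 1) // 50 + 1] = True
        inside, outside = vec[mask], vec[~mask]
        # two-sample comparison: means agree within sampling error
        se = np.hypot(inside.std() / np.sqrt(inside.size), outside.std() / np.sqrt(outside.size))
        assert abs(inside.mean() - outside.mean()) < 4 * se + 1e-12

    def test_nonadditive_pair_routes_to_exactly_one_mark(self):
        cfg = SyntheticConfig(
            seed=8,
            noise_sd=0.0,
            informative_marks={"H3K27Ac": 4.0, "H3K79me3": 4.0},
            nonadditive_pair=("H3K27Ac", "H3K79me3"),
            **SMALL,
        )
        rng = np.random.default_rng(8)
        genome, _ = generate_genome(cfg, rng)
        positives = place_enhancers(cfg, genome, rng)
        tracks = simulate_tracks(cfg, genome, positives, rng)
        t1 = next(t for t in tracks if t.mark == "H3K27Ac").values["chr1"]
        t2 = next(t for t in tracks if t.mark == "H3K79me3").values["chr1"]
        # judge each enhancer at windows no other enhancer touches
        window_sets = [
            set(range(p.start // 50, (p.end - 1) // 50 + 1)) for p in positives
        ]
        seen = {(False, True): 0, (True, False): 0}
        for i, wins in enumerate(window_sets):
            others = set().union(*(w for j, w in enumerate(window_sets) if j != i))
            exclusive = sorted(wins - others)
            assert exclusive, "every enhancer should own at least one window"
            w = exclusive[0]
            key = (t1[w] > 0, t2[w] > 0)
            assert key in seen, "effect must go to exactly one paired mark"
            seen[key] += 1
        assert min(seen.values()) > 0  # both routings occur


class TestDataset:
    def test_directory_contents_and_loadability(self, tmp_path):
        cfg = SyntheticConfig(seed=9, **SMALL)
        ds = generate_dataset(cfg, outdir=tmp_path / "d")
        genome = read_fasta(tmp_path / "d" / "genome.fa")
        assert genome == ds.genome
        positives = read_bed(tmp_path / "d" / "positives.bed", label="positive")
        assert len(positives) == cfg.n_positives
        pwms = read_jaspar_pfm(tmp_path / "d" / "motifs.pfm")
        assert [p.id for p in pwms] == [p.id for p in ds.pwms]
        for mark in cfg.mark_names:
            track = read_bedgraph(tmp_path / "d" / f"{mark}.bedgraph", 50)
            np.testing.assert_allclose(
                track.values["chr1"], ds.tracks[cfg.mark_names.index(mark)].values["chr1"],
                atol=5e-6,  # bedGraph text carries 6 significant digits
            )
        assert ds.truth["driver_motifs"] == ["TF001", "TF002"]

    def test_same_seed_identical_directories(self, tmp_path):
        cfg = SyntheticConfig(seed=10, **SMALL)
        generate_dataset(cfg, outdir=tmp_path / "a")
        generate_dataset(cfg, outdir=tmp_path / "b")
        names = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert sorted(match) == sorted(names) and not mismatch and not errors
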