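import numpy as np
import pytest

from tetermi.gene_annotation import classify_location
from tetermi.synthetic_data import (
    SimConfig,
    generate_chip_tags,
    generate_gene_set,
    generate_pet_library,
    read_ground_truth,
    write_dataset,
    write_ground_truth,
)


def _tiny(**kw):
    base = dict(n_genes=5, n_celltypes=2, genome_length=200_000,
                library_size=5_000, seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_rejects_out_of_range_probabilities(self):
        with pytest.raises(ValueError):
            _tiny(noise_rate=1.5)
        with pytest.raises(ValueError):
            _tiny(te_fraction_of_tts=-0.1)

    def test_rejects_bad_tts_range(self):
        with pytest.raises(ValueError):
            _tiny(tts_per_gene=(3, 1))

    def test_rejects_prob_matrix_rows_summing_past_one(self):
        with pytest.raises(ValueError):
            _tiny(termination_prob_matrix={0: [[0.7, 0.2], [0.6, 0.2]]})

    def test_rejects_genome_too_small_for_genes(self):
        with pytest.raises(ValueError, match="not fit"):
            generate_gene_set(_tiny(genome_length=30_000))


class TestGeneSet:
    def test_zero_genes_empty_everything(self):
        genes, tes, truth = generate_gene_set(_tiny(n_genes=0))
        assert genes == [] and tes == [] and truth.true_tts == []

    def test_te_fraction_one_forces_te_linked_tts(self):
        cfg = _tiny(tts_per_gene=(1, 1), te_fraction_of_tts=1.0,
                    uniform_gene_fraction=0.0, specific_gene_fraction=0.0)
        _, _, truth = generate_gene_set(cfg)
        alts = [t for t in truth.true_tts if not t.is_canonical]
        assert alts and all(t.te_id is not None for t in alts)

    def test_deterministic_given_seed(self, tmp_path):
        cfg = _tiny(seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_dataset(cfg, d1)
        p2 = write_dataset(cfg, d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_loci_do_not_overlap(self):
        genes, _, _ = generate_gene_set(_tiny())
        for a, b in zip(genes, genes[1:]):
            assert a.locus.end <= b.locus.start

    def test_planted_tts_inside_locus_or_downstream_window(self):
        cfg = _tiny(n_genes=20, genome_length=800_000)
        genes, _, truth = generate_gene_set(cfg)
        by_id = {g.id: g for g in genes}
        for t in truth.true_tts:
            g = by_id[t.gene_id]
            d = (t.position - g.annotated_tts) * (1 if g.strand == "+" else -1)
            assert g.locus.contains(t.position) or 0 < d <= cfg.downstream_limit

    def test_te_linked_tts_satisfy_fifty_fifteen_rule(self):
        cfg = _tiny(n_genes=20, genome_length=800_000, te_fraction_of_tts=1.0)
        genes, tes, truth = generate_gene_set(cfg)
        by_gene = {g.id: g for g in genes}
        by_te = {te.id: te for te in tes}
        checked = 0
        for t in truth.true_tts:
            if t.te_id is None:
                continue
            te, g = by_te[t.te_id], by_gene[t.gene_id]
            if g.strand == "+":
                into = t.position - te.span.start
                past = t.position - (te.span.end - 1)
            else:
                into = (te.span.end - 1) - t.position
                past = te.span.start - t.position
            assert into >= 50 and past < 15
            checked += 1
        assert checked > 0

    def test_planted_class_matches_classifier(self):
        genes, _, truth = generate_gene_set(_tiny())
        by_id = {g.id: g for g in genes}
        for t in truth.true_tts:
            assert t.planted_class == classify_location(t.position, by_id[t.gene_id])


class TestPetLibrary:
    def test_degenerate_library_hits_exact_base(self):
        cfg = _tiny(n_genes=1, tts_per_gene=(1, 1), jitter_sd=0.0, noise_rate=0.0,
                    termination_prob_matrix={0: [[1.0, 1.0]]})
        genes, _, truth = generate_gene_set(cfg)
        alt = next(t for t in truth.true_tts if not t.is_canonical)
        lib = generate_pet_library(genes, truth, "ct01", cfg)
        assert len(lib) == cfg.library_size
        assert np.all(lib.three == alt.position)

    def test_binomial_convergence_to_planted_probability(self):
        cfg = _tiny(n_genes=1, tts_per_gene=(1, 1), jitter_sd=0.0, noise_rate=0.0,
                    library_size=10_000, termination_prob_matrix={0: [[0.75, 0.75]]})
        genes, _, truth = generate_gene_set(cfg)
        alt = next(t for t in truth.true_tts if not t.is_canonical)
        lib = generate_pet_library(genes, truth, "ct01", cfg)
        frac = np.mean(lib.three == alt.position)
        assert abs(frac - 0.75) <= 3 * np.sqrt(0.75 * 0.25 / 10_000)

    def test_zero_library_size_empty_stream(self):
        cfg = _tiny(library_size=0)
        genes, _, truth = generate_gene_set(cfg)
        assert len(generate_pet_library(genes, truth, "ct01", cfg)) == 0

    def test_unknown_celltype_rejected(self):
        cfg = _tiny()
        genes, _, truth = generate_gene_set(cfg)
        with pytest.raises(ValueError, match="unknown cell type"):
            generate_pet_library(genes, truth, "nope", cfg)

    def test_tag_conservation(self):
        cfg = _tiny()
        genes, _, truth = generate_gene_set(cfg)
        lib = generate_pet_library(genes, truth, "ct02", cfg)
        assert len(lib) == cfg.library_size
        assert np.bincount(lib.gene_index, minlength=len(genes)).sum() == cfg.library_size


class TestChipTags:
    def test_no_anchors_no_background_is_empty(self):
        cfg = _tiny(chip_background=0.0)
        assert generate_chip_tags([], cfg).size == 0

    def test_pure_enrichment_stays_within_four_sd(self):
        cfg = _tiny(chip_background=0.0, chip_enrichment_height=500.0,
                    chip_enrichment_sd=50.0)
        tags = generate_chip_tags([100_000], cfg)
        assert tags.size > 0
        assert np.all(np.abs(tags - 100_000) <= 4 * 50)

    def test_zero_height_is_flat_background(self):
        cfg = _tiny(chip_enrichment_height=0.0, chip_background=0.01,
                    genome_length=200_000)
        tags = generate_chip_tags([50_000, 100_000], cfg)
        # Poisson bound on total and rough uniformity over halves
        lam = 0.01 * 200_000
        assert abs(tags.size - lam) <= 4 * np.sqrt(lam)
        left = np.sum(tags < 100_000)
        assert abs(left - tags.size / 2) <= 4 * np.sqrt(tags.size) / 2 + 1


class TestGroundTruthSidecar:
    def test_roundtrip(self, tmp_path):
        cfg = _tiny()
        _, _, truth = generate_gene_set(cfg)
        path = tmp_path / "truth.tsv"
        write_ground_truth(truth, path)
        back = read_ground_truth(path)
        assert back.celltypes == truth.celltypes
        assert len(back.true_tts) == len(truth.true_tts)
        for a, b in zip(back.true_tts, truth.true_tts):
            assert a.tts_id == b.tts_id and a.position == b.position
            assert a.te_id == b.te_id and a.pattern == b.pattern
            assert np.allclose(a.probs, b.probs, atol=1e-6)
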