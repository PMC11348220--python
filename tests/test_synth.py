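"""Synthetic generator: molecule sampling, phenotype map, rendering, datasets."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from molimage.graphs import AttributeVocabulary
from molimage.synth import (Phenotype, SynthConfig, generate_dataset,
                            graph_descriptors, phenotype_of,
                            phenotype_signal_r2, render_views,
                            sample_molecule)

from conftest import make_chain


def is_connected(g):
    if g.num_nodes == 1:
        return True
    m = coo_matrix((np.ones(g.num_arcs),
                    (g.edge_index[:, 0], g.edge_index[:, 1])),
                   shape=(g.num_nodes, g.num_nodes))
    return connected_components(m, directed=False)[0] == 1


class TestSampleMolecule:
    def test_deterministic_given_seed(self):
        vocab = AttributeVocabulary((8,), (4,))
        a = sample_molecule((5, 15), vocab, 3)
        b = sample_molecule((5, 15), vocab, 3)
        assert np.array_equal(a.node_attrs, b.node_attrs)
        assert np.array_equal(a.edge_index, b.edge_index)

    def test_exact_size_range(self):
        vocab = AttributeVocabulary((8,), (4,))
        for s in range(10):
            assert sample_molecule((5, 5), vocab, s).num_nodes == 5

    def test_connected_with_degree_cap(self):
        vocab = AttributeVocabulary((8,), (4,))
        for s in range(300):
            g = sample_molecule((2, 20), vocab, s)
            degrees = np.bincount(g.edge_index[:, 0], minlength=g.num_nodes)
            assert degrees.max() <= 4
            assert is_connected(g)


class TestPhenotype:
    def test_alpha_zero_identical_for_all_molecules(self):
        vocab = AttributeVocabulary((12,), (4,))
        phs = {phenotype_of(sample_molecule((5, 20), vocab, s), 0.0, seed=1)
               for s in range(10)}
        assert len(phs) == 1

    def test_isomorphic_graphs_same_phenotype(self):
        g = make_chain(7, atom=3)
        perm = np.random.default_rng(0).permutation(7)
        inv = np.argsort(perm)
        from molimage.graphs import MolecularGraph
        gp = MolecularGraph(g.node_attrs[perm],
                            np.stack([inv[g.edge_index[:, 0]],
                                      inv[g.edge_index[:, 1]]], 1),
                            g.edge_attrs)
        assert phenotype_of(g, 1.0, 0) == phenotype_of(gp, 1.0, 0)

    def test_chain_length_follows_descriptor_map(self):
        """Recompute the map by hand for chains; cell counts must agree."""
        from molimage.synth import _phenotype_map

        w, mean, sd = _phenotype_map(0, 12)
        for n in (4, 8, 16):
            d = graph_descriptors(make_chain(n), 12)
            z0 = np.tanh(w[0] @ ((d - mean) / sd) / np.sqrt(d.size))
            expected = int(np.clip(round(7 + 4 * z0), 1, 14))
            assert phenotype_of(make_chain(n), 1.0, 0).cell_count == expected
        # across typical molecules the map produces genuinely varied counts
        vocab = AttributeVocabulary((12,), (4,))
        counts = {phenotype_of(sample_molecule((5, 20), vocab, s), 1.0, 0)
                  .cell_count for s in range(30)}
        assert len(counts) >= 4

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            phenotype_of(make_chain(3), 1.5, 0)


class TestRendering:
    PH = Phenotype(4, (0.9, 0.6, 0.5, 0.7, 0.8), 1.5)

    def test_five_channels_and_shape(self):
        (v,) = render_views(self.PH, 1, 0.05, 0, 0.1, 24, seed=0)
        assert v.pixels.shape == (5, 24, 24)

    def test_noise_free_views_differ_only_by_placement(self):
        views = render_views(self.PH, 2, 0.0, 0, 0.0, 32, seed=1)
        assert not np.array_equal(views[0].pixels, views[1].pixels)
        assert all(np.all(v.pixels >= 0) for v in views)

    def test_connected_components_match_drawn_cells(self):
        ph = Phenotype(3, (1.0, 1.0, 1.0, 1.0, 1.0), 1.0)
        views, counts = render_views(ph, 5, 0.0, 0, 0.0, 32, seed=2,
                                     return_counts=True)
        for v, c in zip(views, counts):
            dna = v.pixels[0]
            if c == 0:
                assert dna.max() < 1e-9
                continue
            _lab, n = ndimage.label(dna > 0.25 * dna.max())
            assert n == c

    def test_batch_offset_shifts_mean_intensity(self):
        scale = 0.5
        v0 = render_views(self.PH, 1, 0.0, 0, scale, 32, seed=3)[0]
        v1 = render_views(self.PH, 1, 0.0, 1, scale, 32, seed=3)[0]
        from molimage.synth import _BATCH_SALT
        off0 = scale * np.random.default_rng([0, _BATCH_SALT, 0]).normal(size=5)
        off1 = scale * np.random.default_rng([0, _BATCH_SALT, 1]).normal(size=5)
        observed = v1.pixels.mean(axis=(1, 2)) - v0.pixels.mean(axis=(1, 2))
        # same seed -> same cell placement, so the difference is exactly the offset
        assert np.allclose(observed, off1 - off0, atol=1e-9)

    def test_determinism(self):
        a = render_views(self.PH, 2, 0.1, 0, 0.1, 16, seed=4)
        b = render_views(self.PH, 2, 0.1, 0, 0.1, 16, seed=4)
        for x, y in zip(a, b):
            assert np.array_equal(x.pixels, y.pixels)


class TestGenerateDataset:
    def test_manifest_row_count(self, tmp_path):
        cfg = SynthConfig(n_molecules=10, views_per_molecule=4, image_size=16,
                          seed=0)
        ds = generate_dataset(cfg, tmp_path)
        assert len(ds.manifest) == 40 and len(ds.images) == 40
        assert len(ds.pairs) == 40
        assert (tmp_path / "graphs.jsonl").exists()
        assert (tmp_path / "manifest.tsv").exists()

    def test_reruns_byte_identical(self, tmp_path):
        cfg = SynthConfig(n_molecules=6, views_per_molecule=2, image_size=16,
                          seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(cfg, d1)
        generate_dataset(cfg, d2)
        assert (d1 / "graphs.jsonl").read_bytes() == \
            (d2 / "graphs.jsonl").read_bytes()
        assert (d1 / "manifest.tsv").read_bytes() == \
            (d2 / "manifest.tsv").read_bytes()
        for p in sorted((d1 / "images").glob("*.npz")):
            with np.load(p) as a, np.load(d2 / "images" / p.name) as b:
                assert np.array_equal(a["pixels"], b["pixels"])

    def test_round_robin_batches(self):
        cfg = SynthConfig(n_molecules=3, views_per_molecule=6, n_batches=3,
                          image_size=16, seed=1)
        ds = generate_dataset(cfg)
        per_mol = ds.pairs.groupby("molecule_id")["batch_id"].apply(list)
        for batches in per_mol:
            assert batches == [0, 1, 2, 0, 1, 2]

    def test_different_seeds_differ(self):
        a = generate_dataset(SynthConfig(n_molecules=4, views_per_molecule=1,
                                         image_size=16, seed=1))
        b = generate_dataset(SynthConfig(n_molecules=4, views_per_molecule=1,
                                         image_size=16, seed=2))
        assert not np.array_equal(a.images[0].pixels, b.images[0].pixels)

    def test_loader_roundtrip_consistency(self, tmp_path):
        from molimage.graphs import read_graphs
        from molimage.images import ImageManifest, load_images

        cfg = SynthConfig(n_molecules=4, views_per_molecule=2, image_size=16,
                          seed=2)
        ds = generate_dataset(cfg, tmp_path)
        graphs = read_graphs(tmp_path / "graphs.jsonl")
        manifest = ImageManifest.from_tsv(tmp_path / "manifest.tsv")
        manifest.validate_against([g.molecule_id for g in graphs])
        loaded = list(load_images(manifest, root=tmp_path))
        assert len(loaded) == len(ds.images)
        for a, b in zip(loaded, ds.images):
            assert a.molecule_id == b.molecule_id
            assert np.array_equal(a.pixels, b.pixels)

    def test_linear_probe_recovers_signal_only_when_present(self):
        strong = generate_dataset(SynthConfig(n_molecules=120,
                                              views_per_molecule=1,
                                              signal_strength=0.9,
                                              image_size=16, seed=3))
        none = generate_dataset(SynthConfig(n_molecules=120,
                                            views_per_molecule=1,
                                            signal_strength=0.0,
                                            image_size=16, seed=3))
        r2_strong = phenotype_signal_r2(strong.graphs, strong.phenotypes, 12)
        r2_none = phenotype_signal_r2(none.graphs, none.phenotypes, 12)
        assert r2_strong > 0.5
        assert abs(r2_none) < 0.05
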