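"""Superposition, RMSD matrices, Daura clustering and PDB I/O."""

import numpy as np
import pytest

from stepspec.cluster import (
    AtomInfo,
    AtomMask,
    ConformerEnsemble,
    GeometryError,
    cluster_report,
    daura_cluster,
    kabsch_superpose,
    read_multimodel_pdb,
    rmsd_matrix,
    write_multimodel_pdb,
)
from stepspec.synth import default_ligand_atoms, helix_scaffold, simulate_ensemble
from stepspec.duplex import validate_palindrome

from _oracles import daura_reference, quaternion_rmsd


def random_frame(n, rng):
    return rng.normal(scale=5.0, size=(n, 3))


def rigid(coords, rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return coords @ R.T + rng.uniform(-10, 10, size=3)


class TestKabsch:
    def test_self_superposition(self):
        rng = np.random.default_rng(0)
        x = random_frame(12, rng)
        R, t, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-8)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        x = random_frame(20, rng)
        y = rigid(x, rng)
        R, t, rmsd = kabsch_superpose(x, y)
        assert rmsd < 1e-8
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_frame(10, rng), random_frame(10, rng)
        _, _, rmsd = kabsch_superpose(x, y)
        assert rmsd == pytest.approx(quaternion_rmsd(x, y), abs=1e-8)

    def test_rotation_is_always_proper(self):
        # near-planar selections are where reflections would sneak in
        rng = np.random.default_rng(4)
        x = random_frame(6, rng)
        x[:, 2] *= 1e-6
        y = -random_frame(6, rng)
        R, _, _ = kabsch_superpose(x, y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_too_few_atoms(self):
        with pytest.raises(GeometryError, match=">= 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_selection(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch_superpose(line, line)


class TestRmsdMatrix:
    def test_identical_frames_zero_matrix(self):
        rng = np.random.default_rng(2)
        frame = random_frame(8, rng)
        ens = _ensemble(np.stack([frame] * 4))
        assert np.allclose(rmsd_matrix(ens), 0.0, atol=1e-10)

    def test_block_structure_of_rigid_copies(self):
        rng = np.random.default_rng(3)
        a, b = random_frame(10, rng), random_frame(10, rng)
        frames = np.stack([a, rigid(a, rng), b, rigid(b, rng)])
        M = rmsd_matrix(_ensemble(frames))
        assert M[0, 1] < 1e-8 and M[2, 3] < 1e-8
        assert M[0, 2] > 1.0

    def test_consistency_with_pairwise_calls(self):
        rng = np.random.default_rng(5)
        frames = np.stack([random_frame(7, rng) for _ in range(5)])
        ens = _ensemble(frames)
        M = rmsd_matrix(ens)
        assert np.allclose(M, M.T, atol=1e-8)
        for i in range(5):
            for j in range(5):
                _, _, r = kabsch_superpose(frames[i], frames[j])
                assert M[i, j] == pytest.approx(r, abs=1e-12)


def _ensemble(frames):
    n = frames.shape[1]
    atoms = [
        AtomInfo("dna", "A", i + 1, "C1'", "A") for i in range(n)
    ]
    return ConformerEnsemble(coords=frames, atoms=atoms)


class TestDaura:
    def test_everything_within_cutoff(self):
        M = np.full((5, 5), 0.3)
        np.fill_diagonal(M, 0.0)
        c = daura_cluster(M, 1.0)
        assert len(c.clusters) == 1
        assert c.occupancies == [1.0]

    def test_two_tight_triplets(self):
        M = np.full((6, 6), 9.0)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    M[i, j] = 0.2 if i != j else 0.0
        c = daura_cluster(M, 1.0)
        assert [set(cl.members) for cl in c.clusters] == [
            {0, 1, 2}, {3, 4, 5},
        ]
        assert c.occupancies == [0.5, 0.5]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        F = int(rng.integers(2, 9))
        D = rng.uniform(0, 3, size=(F, F))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        cutoff = float(rng.uniform(0.2, 2.5))
        ours = [sorted(c.members) for c in daura_cluster(D, cutoff).clusters]
        assert ours == daura_reference(D, cutoff)

    def test_determinism(self):
        rng = np.random.default_rng(9)
        D = rng.uniform(0, 2, size=(10, 10))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        a = daura_cluster(D, 1.0)
        b = daura_cluster(D.copy(), 1.0)
        assert [c.members for c in a.clusters] == [c.members for c in b.clusters]

    @pytest.mark.parametrize("seed", range(10))
    def test_cutoff_limits(self, seed):
        """Cutoff above every distance gives one cluster; below every
        positive distance, all singletons.  (Strict monotonicity of the
        cluster count in the cutoff does NOT hold for the greedy
        algorithm on arbitrary matrices — the greedy choice can
        reshuffle — so only the limits are asserted here.)"""
        rng = np.random.default_rng(100 + seed)
        F = 12
        D = rng.uniform(0.1, 3, size=(F, F))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        assert len(daura_cluster(D, D.max() + 0.1).clusters) == 1
        off_diag = D[~np.eye(F, dtype=bool)]
        assert len(daura_cluster(D, off_diag.min() / 2).clusters) == F

    @pytest.mark.parametrize("seed", range(5))
    def test_cutoff_monotone_on_separated_blocks(self, seed):
        """On well-separated block matrices a smaller cutoff can only
        split blocks, never merge them."""
        rng = np.random.default_rng(200 + seed)
        sizes = rng.integers(2, 5, size=3)
        F = int(sizes.sum())
        D = np.full((F, F), 10.0)
        start = 0
        for s in sizes:
            block = rng.uniform(0.1, 2.0, size=(s, s))
            block = (block + block.T) / 2
            np.fill_diagonal(block, 0)
            D[start:start + s, start:start + s] = block
            start += s
        counts = [
            len(daura_cluster(D, c).clusters)
            for c in (5.0, 2.5, 1.5, 0.8, 0.3)
        ]
        assert counts == sorted(counts)

    def test_sizes_non_increasing_and_partition(self):
        rng = np.random.default_rng(8)
        D = rng.uniform(0, 2, size=(20, 20))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        c = daura_cluster(D, 0.8)
        sizes = [cl.size for cl in c.clusters]
        assert sizes == sorted(sizes, reverse=True)
        members = sorted(m for cl in c.clusters for m in cl.members)
        assert members == list(range(20))
        assert sum(c.occupancies) == pytest.approx(1.0)

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            daura_cluster(D, 1.0)


class TestClusterReport:
    def test_single_cluster_trivial(self):
        rng = np.random.default_rng(12)
        frame = random_frame(9, rng)
        ens = _ensemble(np.stack([frame] * 5))
        clustering = daura_cluster(rmsd_matrix(ens), 1.0)
        report = cluster_report(ens, clustering)
        assert report.top_occupancy_percent == 100.0
        assert report.clusters[0].mean_rmsd_to_representative == pytest.approx(
            0.0, abs=1e-10
        )

    def test_planted_occupancies_recovered(self):
        ens, labels = simulate_ensemble(
            3, [0.6, 0.3, 0.1], spread=0.3, separation=2.0,
            n_frames=60, seed=21,
        )
        clustering = daura_cluster(rmsd_matrix(ens), 1.5)
        assert len(clustering.clusters) == 3
        for occ, w in zip(clustering.occupancies, [0.6, 0.3, 0.1]):
            assert occ == pytest.approx(w, abs=0.05)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, clustering.labels()) >= 0.95

    def test_central_mask_discounts_terminal_noise(self):
        duplex = validate_palindrome("CCCTAGGG")
        scaffold = helix_scaffold(
            duplex, ligand_atoms=default_ligand_atoms(duplex)
        )
        base = scaffold.coords[0]
        terminal = np.array([
            a.molecule == "dna" and a.residue in (1, 2, 7, 8)
            for a in scaffold.atoms
        ])
        rng = np.random.default_rng(13)
        frames = np.stack([base.copy() for _ in range(6)])
        for f in range(1, 6):  # perturb only the terminal residues
            frames[f][terminal] += rng.normal(scale=1.5, size=(terminal.sum(), 3))
        ens = ConformerEnsemble(coords=frames, atoms=list(scaffold.atoms))
        clustering = daura_cluster(rmsd_matrix(ens), cutoff=50.0)
        central = AtomMask.residues(3, 6) | AtomMask.ligand()
        report = cluster_report(
            ens, clustering, mask=AtomMask.all(), score_mask=central
        )
        c = report.clusters[0]
        assert c.rescored_mean_rmsd < c.mean_rmsd_to_representative


class TestMask:
    def test_parse_grammar(self):
        duplex = validate_palindrome("CCCTAGGG")
        ens = helix_scaffold(duplex, ligand_atoms=default_ligand_atoms(duplex))
        central = AtomMask.parse("resid 3-6 or ligand").apply(ens)
        manual = (AtomMask.residues(3, 6) | AtomMask.ligand()).apply(ens)
        assert (central == manual).all()
        heavy_a = AtomMask.parse("strand A and heavy").apply(ens)
        # P and C1' per residue, plus the carbon-centred CH3 pseudo-atom
        # of each thymine
        n_thy = duplex.top_strand.count("T")
        assert heavy_a.sum() == 2 * duplex.length + n_thy

    def test_parse_rejects_unknown_term(self):
        with pytest.raises(ValueError):
            AtomMask.parse("backbone")

    def test_degenerate_mask_raises_geometry_error(self):
        rng = np.random.default_rng(17)
        ens = _ensemble(np.stack([random_frame(5, rng)] * 2))
        tiny = AtomMask(lambda a: a.residue == 1, "one atom")
        with pytest.raises(GeometryError):
            rmsd_matrix(ens, tiny)


class TestPdbIO:
    def test_round_trip_precision(self, tmp_path):
        ens, _ = simulate_ensemble(
            2, [0.5, 0.5], spread=0.2, separation=2.0, n_frames=2, seed=3
        )
        path = tmp_path / "two.pdb"
        write_multimodel_pdb(ens, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == 2
        assert np.abs(back.coords - ens.coords).max() < 1e-3 + 5e-4

    def test_single_model(self, tmp_path):
        duplex = validate_palindrome("CCCGGG")
        ens = helix_scaffold(duplex)
        path = tmp_path / "one.pdb"
        write_multimodel_pdb(ens, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == 1
        assert len(back.atoms) == ens.n_atoms

    def test_fifty_models_order_and_metadata(self, tmp_path):
        ens, _ = simulate_ensemble(
            2, [0.5, 0.5], spread=0.2, separation=2.0, n_frames=50, seed=5
        )
        path = tmp_path / "fifty.pdb"
        write_multimodel_pdb(ens, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == 50
        assert [
            (a.molecule, a.strand, a.residue, a.name) for a in back.atoms
        ] == [(a.molecule, a.strand, a.residue, a.name) for a in ens.atoms]

    def test_inconsistent_models_rejected(self, tmp_path):
        duplex = validate_palindrome("CCCGGG")
        ens = helix_scaffold(duplex)
        path = tmp_path / "bad.pdb"
        write_multimodel_pdb(ens, path)
        text = path.read_text().splitlines()
        # drop one ATOM record from the (single) model, then duplicate it
        atoms = [l for l in text if l.startswith("ATOM")]
        model2 = ["MODEL        2", *atoms[:-1], "ENDMDL"]
        full = []
        for line in text:
            if line.startswith("END") and not line.startswith("ENDMDL"):
                full.extend(model2)
            full.append(line)
        bad = tmp_path / "inconsistent.pdb"
        bad.write_text("\n".join(full) + "\n")
        with pytest.raises(ValueError, match="inconsistent"):
            read_multimodel_pdb(bad)
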