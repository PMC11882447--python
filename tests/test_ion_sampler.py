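import numpy as np
import pytest

from hydronet.ion_sampler import (
    DefaultScorer,
    Grid3D,
    GridError,
    IonPose,
    SamplerConfig,
    ScorerParams,
    bulk_reference,
    cluster_poses,
    dense_scan,
    generate_grid,
    occupancy,
    run_two_stage,
    scaling_sensitivity,
)
from hydronet.structure_io import Atom, Residue, StructureModel

RT = 0.593


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("extent,spacing,count", [
    (2.5, 0.5, 1331),   # coarse stage
    (0.2, 0.05, 729),   # fine stage (x10 clusters = 7,290)
    (0.0, 0.1, 1),      # degenerate: just the center
])
def test_grid_counts(extent, spacing, count):
    grid = Grid3D((0, 0, 0), extent, spacing)
    pts = generate_grid(grid)
    assert grid.n_positions == count == len(pts)


def test_grid_rejects_offgrid_endpoints():
    with pytest.raises(GridError):
        Grid3D((0, 0, 0), 2.5, 0.4)


def test_grid_order_and_center():
    pts = generate_grid(Grid3D((1.0, 2.0, 3.0), 0.5, 0.5))
    assert len(pts) == 27
    np.testing.assert_allclose(pts[0], [0.5, 1.5, 2.5])
    np.testing.assert_allclose(pts[-1], [1.5, 2.5, 3.5])
    # lexicographic ordering
    assert sorted(map(tuple, pts)) == list(map(tuple, pts))


# ---------------------------------------------------------------------------
# Default scorer
# ---------------------------------------------------------------------------


def _asp_oxygen(pos):
    return Residue("A", 1, "", "ASP", [
        Atom(1, "OD1", "O", np.asarray(pos, float)),
    ])


def _carbon(pos):
    return Residue("A", 2, "", "ALA", [Atom(2, "CB", "C", np.asarray(pos, float))])


def test_scorer_empty_model_no_shell_is_zero():
    scorer = DefaultScorer(ScorerParams(shell_enabled=False))
    assert scorer.score(StructureModel("e", []), np.zeros(3)) == 0.0


def test_scorer_carboxylate_attraction():
    scorer = DefaultScorer(ScorerParams(shell_enabled=False))
    model = StructureModel("m", [_asp_oxygen((2.3, 0, 0))])
    assert scorer.score(model, np.zeros(3)) < -2.0


def test_scorer_clash_is_large_positive_and_finite():
    scorer = DefaultScorer(ScorerParams(shell_enabled=False))
    model = StructureModel("m", [_carbon((1.0, 0, 0))])
    s = scorer.score(model, np.zeros(3))
    assert 50 < s < np.inf


def test_scorer_deterministic_and_vector_consistent():
    fx_model = StructureModel("m", [_asp_oxygen((2.3, 0, 0)), _carbon((0, 3.2, 0))])
    scorer = DefaultScorer()
    pts = generate_grid(Grid3D((0, 0, 0), 1.0, 0.5))
    many = scorer.score_many(fx_model, pts)
    singles = [scorer.score(fx_model, p) for p in pts]
    np.testing.assert_allclose(many, singles, rtol=1e-12)
    np.testing.assert_allclose(many, scorer.score_many(fx_model, pts))


# ---------------------------------------------------------------------------
# Pose clustering
# ---------------------------------------------------------------------------


def _pose(pos, score, dvec=()):
    return IonPose(np.asarray(pos, float), score, np.asarray(dvec, float))


def test_cluster_identical_poses_single_cluster():
    poses = [_pose((1, 1, 1), -2.0) for _ in range(5)]
    clusters = cluster_poses(poses)
    assert len(clusters) == 1
    assert clusters[0].best_score == -2.0


def test_cluster_two_separated_groups():
    poses = [_pose((0, 0, 0), -1.0), _pose((0.2, 0, 0), -3.0),
             _pose((10, 0, 0), -2.0), _pose((10.2, 0, 0), -0.5)]
    clusters = cluster_poses(poses, cut=1.0)
    assert len(clusters) == 2
    assert clusters[0].best_score == -3.0  # ranked by best member


def test_cluster_top_k_selection():
    poses = [_pose((10 * i, 0, 0), float(i)) for i in range(15)]
    clusters = cluster_poses(poses, cut=1.0, top_k=10)
    assert len(clusters) == 10
    assert [c.best_score for c in clusters] == list(map(float, range(10)))


def test_cluster_distance_vector_separates_equal_positions():
    # same ion position but very different residue-contact signatures
    poses = [_pose((0, 0, 0), -1.0, (2.0, 2.0)),
             _pose((0, 0, 0), -2.0, (8.0, 8.0))]
    assert len(cluster_poses(poses, cut=1.0)) == 2


def test_cluster_empty_errors():
    with pytest.raises(ValueError):
        cluster_poses([])


# ---------------------------------------------------------------------------
# Two-stage protocol on the planted cage (session fixture)
# ---------------------------------------------------------------------------


def test_two_stage_evaluation_counts(ion_fixture):
    result = run_two_stage(
        ion_fixture.model, ion_fixture.site_center,
        config=SamplerConfig(site_residues=ion_fixture.site_residues),
    )
    assert len(result.coarse_poses) == 1331
    assert len(result.selected_clusters) <= 10
    assert len(result.fine_poses) == 729 * len(result.selected_clusters)
    assert len(result.final_top) == 10
    scores = [p.score for p in result.final_top]
    assert scores == sorted(scores)


def test_two_stage_refinement_never_worse_than_coarse(ion_fixture):
    result = run_two_stage(
        ion_fixture.model, ion_fixture.site_center,
        config=SamplerConfig(site_residues=ion_fixture.site_residues),
    )
    assert result.site_energy <= min(p.score for p in result.coarse_poses)


def test_two_stage_deterministic(ion_fixture):
    cfg = SamplerConfig(site_residues=ion_fixture.site_residues)
    r1 = run_two_stage(ion_fixture.model, ion_fixture.site_center, config=cfg)
    r2 = run_two_stage(ion_fixture.model, ion_fixture.site_center, config=cfg)
    np.testing.assert_array_equal(r1.best_position, r2.best_position)
    assert [p.score for p in r1.final_top] == [p.score for p in r2.final_top]


def test_two_stage_matches_dense_scan(ion_fixture):
    result = run_two_stage(
        ion_fixture.model, ion_fixture.site_center,
        config=SamplerConfig(site_residues=ion_fixture.site_residues),
    )
    dense_pos, dense_score = dense_scan(
        ion_fixture.model, ion_fixture.site_center, extent=2.5, spacing=0.05
    )
    assert np.linalg.norm(result.best_position - dense_pos) <= 0.05
    assert result.site_energy <= dense_score + 0.5


# ---------------------------------------------------------------------------
# Bulk reference and occupancy
# ---------------------------------------------------------------------------


def test_bulk_reference_shell_disabled_is_zero():
    ref = bulk_reference(DefaultScorer(ScorerParams(shell_enabled=False)))
    assert ref.energy == 0.0


def test_bulk_reference_prefers_six_waters():
    ref = bulk_reference()
    assert ref.n_waters == 6
    assert all(ref.energy <= e for e in ref.energies_by_n.values())


def test_occupancy_zero_delta_is_half():
    assert occupancy(0.0, 0.0).occupancy == pytest.approx(0.5)


def test_occupancy_closed_form():
    # kappa*dE = -RT ln 9  ->  occupancy 0.9
    dE = -RT * np.log(9.0)
    assert occupancy(dE, 0.0, kappa=1.0, RT=RT).occupancy == pytest.approx(0.9)


def test_occupancy_symmetry_and_monotonicity():
    for dE in (-3.0, -0.5, 0.0, 0.7, 4.0):
        assert occupancy(dE, 0.0).occupancy + occupancy(-dE, 0.0).occupancy == pytest.approx(1.0)
    occs = [occupancy(dE, 0.0).occupancy for dE in np.linspace(-5, 5, 21)]
    assert occs == sorted(occs, reverse=True)
    assert all(0 < o < 1 for o in occs)


def test_occupancy_rejects_bad_params():
    with pytest.raises(ValueError):
        occupancy(0.0, 0.0, kappa=-1.0)


def test_scaling_sensitivity_rank_invariance():
    designs = [("d1", -2.0), ("d2", 0.0), ("d3", 1.0), ("d4", 3.5), ("d5", -0.7)]
    table, stable = scaling_sensitivity(designs, kappas=(1.0, 2.0, 3.0))
    assert stable
    for kappa in (1.0, 3.0):
        occs = [table[d][kappa] for d, _ in sorted(designs, key=lambda t: t[1])]
        assert occs == sorted(occs, reverse=True)  # decreasing in dE
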