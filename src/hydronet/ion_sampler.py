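"""Two-stage voxel-grid sampling of buried ion placements.

The protocol mirrors grid-based ion modelling in design pipelines:

1. score the ion exhaustively on a coarse voxel grid (0.5 A spacing over a
   +/-2.5 A box = 1,331 placements) around the putative binding site;
2. cluster the scored poses hierarchically on a combined position +
   residue-distance-vector metric and keep the ten best-scoring clusters;
3. rescore a fine grid (0.05 A spacing over +/-0.2 A = 729 placements) around
   each selected cluster centroid (7,290 evaluations for ten clusters);
4. keep the ten best fine poses.

Binding is summarised as a Boltzmann occupancy of the site versus the ion
fully solvated in bulk, with a configurable REU -> kcal/mol scale factor
kappa; conclusions should be checked for stability over kappa in [1, 3].

The bundled :class:`DefaultScorer` is a deliberately simple, fully documented
rigid-receptor potential (screened Coulomb + soft-sphere repulsion + a
first-shell water completion term); any object satisfying the scorer contract
(deterministic ``score(model, position)``) can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist

from .hbond import polar_atom_table
from .structure_io import StructureModel

RT_298K = 0.593  # kcal/mol at 298 K


class GridError(ValueError):
    """Raised for inconsistent grid specifications."""


@dataclass(frozen=True)
class Grid3D:
    """Cubic voxel grid: center +/- extent at the given spacing (inclusive)."""

    center: tuple[float, float, float]
    extent: float  # half-width, Angstrom
    spacing: float  # Angstrom

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GridError("spacing must be positive")
        if self.extent < 0:
            raise GridError("extent must be non-negative")
        ratio = self.extent / self.spacing
        if abs(ratio - round(ratio)) > 1e-9:
            raise GridError(
                f"extent/spacing = {ratio} is not an integer: endpoints would fall "
                "off-grid"
            )

    @property
    def points_per_axis(self) -> int:
        return 2 * round(self.extent / self.spacing) + 1

    @property
    def n_positions(self) -> int:
        return self.points_per_axis**3


def generate_grid(grid: Grid3D) -> np.ndarray:
    """All grid positions in lexicographic (x, y, z) order, shape (n, 3)."""
    k = round(grid.extent / grid.spacing)
    axis = np.arange(-k, k + 1) * grid.spacing
    xs, ys, zs = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    return pts + np.asarray(grid.center, dtype=float)


# ---------------------------------------------------------------------------
# Default scorer
# ---------------------------------------------------------------------------

# Partial charges (e) on polar heavy atoms seen by the ion.
_CHARGE_BY_ATOM: dict[tuple[str, str], float] = {}
for _res, _atoms in (
    ("ASP", ("OD1", "OD2")),
    ("GLU", ("OE1", "OE2")),
):
    for _a in _atoms:
        _CHARGE_BY_ATOM[(_res, _a)] = -0.5  # carboxylate oxygens

_POLAR_O_CHARGE = -0.40  # neutral acceptor oxygens (backbone O, hydroxyls, amide O)
_POLAR_N_CHARGE = +0.30  # donor nitrogens

# Soft-sphere contact radii versus a Na+-sized cation, by element.
_CONTACT_RADIUS = {"O": 2.25, "N": 2.45, "S": 2.80, "C": 3.00, "H": 1.80}
_DEFAULT_CONTACT = 2.90


@dataclass
class ScorerParams:
    """All constants of the default potential (REU, Angstrom, e)."""

    ion_charge: float = +1.0
    coulomb_k: float = 332.0  # kcal*A/(mol*e^2)
    dielectric_slope: float = 10.0  # eps(r) = slope * r (distance-dependent)
    elec_cutoff: float = 8.0
    min_r: float = 0.5  # clamp: keeps energies finite at overlap
    k_rep: float = 20.0  # REU / A^2 soft-sphere constant
    shell_distance: float = 2.3  # ideal ion-water oxygen distance
    shell_energy: float = -1.5  # REU per completed first-shell water
    shell_exclusion: float = 2.6  # site blocked if a heavy atom is closer
    shell_enabled: bool = True
    water_contact: float = 2.7  # water-water soft-sphere contact distance


# Octahedral first-shell directions plus two cube-diagonal overflow sites
# used when enumerating bulk coordination numbers above six.
_SHELL_DIRECTIONS = np.array(
    [
        [1, 0, 0], [-1, 0, 0],
        [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1],
        [0.57735027, 0.57735027, 0.57735027],
        [-0.57735027, -0.57735027, -0.57735027],
    ]
)


class DefaultScorer:
    """Deterministic rigid-receptor ion scorer.

    Energy of an ion at position x:

    ``E(x) = sum_i k_c * q_ion * q_i / (slope * r_i^2)``   (screened Coulomb,
    distance-dependent dielectric ``eps = slope * r``, atoms within 8 A,
    ``r`` clamped at ``min_r``)

    ``     + sum_i k_rep * (r0_i - r_i)^2  for r_i < r0_i``  (soft-sphere)

    ``     + n_shell(x) * shell_energy``  (first-shell completion: up to six
    octahedral water sites at 2.3 A from the ion, each counted when no model
    heavy atom lies within the exclusion radius of the site).

    All constants live in :class:`ScorerParams`; identical inputs always give
    identical output and every score is finite.
    """

    def __init__(self, params: ScorerParams | None = None) -> None:
        self.params = params or ScorerParams()
        self._cache_key: int | None = None
        self._atoms: np.ndarray | None = None
        self._charges: np.ndarray | None = None
        self._radii: np.ndarray | None = None

    # -- model preprocessing -------------------------------------------------

    def _prepare(self, model: StructureModel) -> None:
        if self._cache_key == id(model):
            return
        pos, q, r0 = [], [], []
        for res in model.residues:
            roles = polar_atom_table(res.name) if not res.is_water else {"O": "both"}
            for a in res.atoms:
                if a.element == "H":
                    continue
                pos.append(a.position)
                r0.append(_CONTACT_RADIUS.get(a.element, _DEFAULT_CONTACT))
                charge = _CHARGE_BY_ATOM.get((res.name, a.name))
                if charge is None:
                    role = roles.get(a.name)
                    if role is None:
                        charge = 0.0
                    elif a.element == "O" or a.element == "S":
                        charge = _POLAR_O_CHARGE
                    else:
                        charge = _POLAR_N_CHARGE
                q.append(charge)
        self._atoms = np.array(pos) if pos else np.zeros((0, 3))
        self._charges = np.array(q)
        self._radii = np.array(r0)
        self._tree = cKDTree(self._atoms) if len(self._atoms) else None
        self._cache_key = id(model)

    # -- scoring -------------------------------------------------------------

    def score_many(self, model: StructureModel, positions: np.ndarray) -> np.ndarray:
        """Vectorised scores for positions of shape (n, 3)."""
        self._prepare(model)
        p = self.params
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        out = np.zeros(n)
        atoms, q, r0 = self._atoms, self._charges, self._radii
        # chunking bounds the (chunk, n_atoms) distance matrix
        chunk = max(1, int(2e6 / max(1, len(atoms))))
        for lo in range(0, n, chunk):
            pts = positions[lo : lo + chunk]
            if len(atoms):
                d = cdist(pts, atoms)
                dc = np.maximum(d, p.min_r)
                elec = np.where(
                    d <= p.elec_cutoff,
                    p.coulomb_k * p.ion_charge * q[None, :] / (p.dielectric_slope * dc**2),
                    0.0,
                ).sum(axis=1)
                overlap = np.maximum(r0[None, :] - d, 0.0)
                rep = (p.k_rep * overlap**2).sum(axis=1)
            else:
                elec = rep = np.zeros(len(pts))
            shell = self._shell_term_many(pts)
            out[lo : lo + chunk] = elec + rep + shell
        return out

    def _shell_term_many(self, positions: np.ndarray) -> np.ndarray:
        p = self.params
        if not p.shell_enabled:
            return np.zeros(len(positions))
        if self._tree is None:
            return np.full(len(positions), 6) * p.shell_energy
        sites = (
            positions[:, None, :]
            + _SHELL_DIRECTIONS[None, :6, :] * p.shell_distance
        ).reshape(-1, 3)
        nearest, _ = self._tree.query(sites, k=1)
        allowed = (nearest.reshape(-1, 6) >= p.shell_exclusion).sum(axis=1)
        return allowed * p.shell_energy

    def score(self, model: StructureModel, position: np.ndarray) -> float:
        return float(self.score_many(model, position)[0])

    def shell_waters(self, model: StructureModel, position: np.ndarray) -> np.ndarray:
        """Positions of the allowed first-shell waters at one ion position."""
        self._prepare(model)
        p = self.params
        position = np.asarray(position, dtype=float)
        sites = position[None, :] + _SHELL_DIRECTIONS[:6] * p.shell_distance
        if not p.shell_enabled:
            return np.zeros((0, 3))
        if len(self._atoms):
            d = np.linalg.norm(sites[:, None, :] - self._atoms[None, :, :], axis=2)
            keep = d.min(axis=1) >= p.shell_exclusion
        else:
            keep = np.ones(6, dtype=bool)
        return sites[keep]

    # -- bulk coordination enumeration ----------------------------------------

    def coordination_energy(self, n_waters: int) -> float:
        """Ion-water energy of an n-water first shell around a bare ion.

        Shell waters sit at the ideal distance along octahedral directions
        (overflow sites 7 and 8 on cube diagonals); water-water soft-sphere
        repulsion penalises overcrowding.
        """
        if not 0 <= n_waters <= len(_SHELL_DIRECTIONS):
            raise ValueError("coordination number out of range")
        p = self.params
        if not p.shell_enabled or n_waters == 0:
            return 0.0
        sites = _SHELL_DIRECTIONS[:n_waters] * p.shell_distance
        e = n_waters * p.shell_energy
        if n_waters > 1:
            d = pdist(sites)
            overlap = np.maximum(p.water_contact - d, 0.0)
            e += float((p.k_rep * overlap**2).sum())
        return e


# ---------------------------------------------------------------------------
# Poses, clustering, two-stage protocol
# ---------------------------------------------------------------------------


@dataclass
class IonPose:
    position: np.ndarray
    score: float
    distance_vector: np.ndarray  # per site residue: ion -> nearest polar heavy atom


@dataclass
class PoseCluster:
    members: list[IonPose]
    centroid: np.ndarray
    best_score: float


@dataclass
class IonSamplingResult:
    coarse_poses: list[IonPose]
    selected_clusters: list[PoseCluster]
    fine_poses: list[IonPose]
    final_top: list[IonPose]

    @property
    def site_energy(self) -> float:
        return self.final_top[0].score

    @property
    def best_position(self) -> np.ndarray:
        return self.final_top[0].position


@dataclass
class SamplerConfig:
    coarse_extent: float = 2.5
    coarse_spacing: float = 0.5
    fine_extent: float = 0.2
    fine_spacing: float = 0.05
    cluster_cut: float = 1.0  # Angstrom, tree cut on the combined metric
    top_k_clusters: int = 10
    top_k_final: int = 10
    lam: float = 1.0  # weight of the distance-vector term in the pose metric
    cluster_rank: str = "best"  # best | mean member score
    fine_center: str = "best_member"  # best_member | centroid
    site_residues: list[tuple[str, int]] = field(default_factory=list)


def _site_polar_positions(
    model: StructureModel, site_residues: list[tuple[str, int]]
) -> list[np.ndarray]:
    """Polar heavy-atom coordinates per site residue (fixed residue order)."""
    out = []
    for chain, resnum in site_residues:
        res = model.residue(chain, resnum)
        if res is None:
            raise ValueError(f"site residue {chain}{resnum} absent from model")
        roles = polar_atom_table(res.name)
        pts = [a.position for a in res.atoms if a.name in roles]
        if not pts:
            pts = [a.position for a in res.atoms]
        out.append(np.array(pts))
    return out


def _make_poses(
    positions: np.ndarray,
    scores: np.ndarray,
    site_atoms: list[np.ndarray],
) -> list[IonPose]:
    if site_atoms:
        dvecs = np.stack(
            [
                np.linalg.norm(positions[:, None, :] - pts[None, :, :], axis=2).min(axis=1)
                for pts in site_atoms
            ],
            axis=1,
        )
    else:
        dvecs = np.zeros((len(positions), 0))
    return [
        IonPose(position=positions[i], score=float(scores[i]), distance_vector=dvecs[i])
        for i in range(len(positions))
    ]


def cluster_poses(
    poses: list[IonPose],
    cut: float = 1.0,
    top_k: int = 10,
    lam: float = 1.0,
    rank: str = "best",
) -> list[PoseCluster]:
    """Average-linkage clustering of poses; keep the ``top_k`` best clusters.

    Pairwise metric: ``|dx| + lam * |d(dvec)| / sqrt(L)`` where L is the
    distance-vector length; the tree is cut at ``cut``.  Clusters are ranked
    by their best (default) or mean member score, ascending.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    pos = np.array([p.position for p in poses])
    dv = np.array([p.distance_vector for p in poses])
    if len(poses) == 1:
        labels = np.array([1])
    else:
        dist = pdist(pos)
        if dv.shape[1] > 0:
            dist = dist + lam * pdist(dv) / np.sqrt(dv.shape[1])
        labels = fcluster(linkage(dist, method="average"), t=cut, criterion="distance")
    clusters: list[PoseCluster] = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        members = [poses[i] for i in idx]
        clusters.append(
            PoseCluster(
                members=members,
                centroid=pos[idx].mean(axis=0),
                best_score=min(m.score for m in members),
            )
        )
    if rank == "best":
        key = lambda c: c.best_score  # noqa: E731
    elif rank == "mean":
        key = lambda c: float(np.mean([m.score for m in c.members]))  # noqa: E731
    else:
        raise ValueError(f"unknown cluster rank {rank!r}")
    clusters.sort(key=lambda c: (key(c), tuple(np.round(c.centroid, 6))))
    return clusters[:top_k]


def run_two_stage(
    model: StructureModel,
    site_center: np.ndarray,
    scorer: DefaultScorer | None = None,
    config: SamplerConfig | None = None,
) -> IonSamplingResult:
    """Full coarse-grid -> cluster -> fine-grid -> top-poses protocol."""
    scorer = scorer or DefaultScorer()
    config = config or SamplerConfig()
    site_center = np.asarray(site_center, dtype=float)
    site_atoms = _site_polar_positions(model, config.site_residues)

    coarse_grid = Grid3D(tuple(site_center), config.coarse_extent, config.coarse_spacing)
    coarse_pts = generate_grid(coarse_grid)
    coarse_scores = scorer.score_many(model, coarse_pts)
    if not np.all(np.isfinite(coarse_scores)):
        bad = coarse_pts[~np.isfinite(coarse_scores)][0]
        raise RuntimeError(f"scorer returned non-finite energy at {bad}")
    coarse_poses = _make_poses(coarse_pts, coarse_scores, site_atoms)

    clusters = cluster_poses(
        coarse_poses,
        cut=config.cluster_cut,
        top_k=config.top_k_clusters,
        lam=config.lam,
        rank=config.cluster_rank,
    )

    fine_poses: list[IonPose] = []
    for cl in clusters:
        # refining around the best member keeps each selected coarse optimum
        # inside its fine grid, so refinement can never lose it
        if config.fine_center == "best_member":
            center = min(cl.members, key=lambda m: m.score).position
        elif config.fine_center == "centroid":
            center = cl.centroid
        else:
            raise ValueError(f"unknown fine_center {config.fine_center!r}")
        fine_grid = Grid3D(tuple(center), config.fine_extent, config.fine_spacing)
        pts = generate_grid(fine_grid)
        scores = scorer.score_many(model, pts)
        if not np.all(np.isfinite(scores)):
            bad = pts[~np.isfinite(scores)][0]
            raise RuntimeError(f"scorer returned non-finite energy at {bad}")
        fine_poses.extend(_make_poses(pts, scores, site_atoms))

    order = sorted(
        range(len(fine_poses)),
        key=lambda i: (fine_poses[i].score, tuple(np.round(fine_poses[i].position, 9))),
    )
    final_top = [fine_poses[i] for i in order[: config.top_k_final]]
    return IonSamplingResult(
        coarse_poses=coarse_poses,
        selected_clusters=clusters,
        fine_poses=fine_poses,
        final_top=final_top,
    )


def dense_scan(
    model: StructureModel,
    site_center: np.ndarray,
    scorer: DefaultScorer | None = None,
    extent: float = 2.5,
    spacing: float = 0.05,
    refine_spacing: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Independent brute-force grid optimum, for cross-checking the sampler.

    Scans the full box at ``spacing`` and then a +/-(6*refine_spacing)
    neighbourhood of the best point at ``refine_spacing``.
    """
    scorer = scorer or DefaultScorer()
    site_center = np.asarray(site_center, dtype=float)
    pts = generate_grid(Grid3D(tuple(site_center), extent, spacing))
    scores = scorer.score_many(model, pts)
    best = pts[int(np.argmin(scores))]
    fine = generate_grid(Grid3D(tuple(best), 6 * refine_spacing, refine_spacing))
    fscores = scorer.score_many(model, fine)
    i = int(np.argmin(fscores))
    return fine[i], float(fscores[i])


# ---------------------------------------------------------------------------
# Bulk reference and occupancy
# ---------------------------------------------------------------------------


@dataclass
class BulkReference:
    energy: float  # REU, ion-water energy of the optimal shell
    n_waters: int
    box_edge: float
    energies_by_n: dict[int, float]


def bulk_reference(scorer: DefaultScorer | None = None, box_edge: float = 5.0) -> BulkReference:
    """Optimal ion-water energy of the ion solvated alone in a cubic box.

    Enumerates first-shell coordination numbers 0..8 with ideal geometry and
    returns the minimum (ties to the smaller shell).
    """
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    scorer = scorer or DefaultScorer()
    energies = {n: scorer.coordination_energy(n) for n in range(9)}
    best_n = min(energies, key=lambda n: (energies[n], n))
    return BulkReference(
        energy=energies[best_n],
        n_waters=best_n,
        box_edge=box_edge,
        energies_by_n=energies,
    )


@dataclass
class OccupancyResult:
    delta_E: float  # REU, site - bulk
    kappa: float  # kcal/mol per REU
    RT: float  # kcal/mol
    occupancy: float


def occupancy(
    site_energy: float,
    bulk_energy: float,
    kappa: float = 1.0,
    RT: float = RT_298K,
) -> OccupancyResult:
    """Two-state Boltzmann occupancy of the site versus bulk.

    ``occ = 1 / (1 + exp(kappa * dE / RT))`` with ``dE = site - bulk``:
    a site more favourable than bulk (dE < 0) is occupied more than half the
    time.
    """
    if kappa <= 0 or RT <= 0:
        raise ValueError("kappa and RT must be positive")
    dE = site_energy - bulk_energy
    occ = 1.0 / (1.0 + np.exp(np.clip(kappa * dE / RT, -700, 700)))
    return OccupancyResult(delta_E=dE, kappa=kappa, RT=RT, occupancy=float(occ))


def scaling_sensitivity(
    designs: list[tuple[str, float]],
    kappas: tuple[float, ...] = (1.0, 2.0, 3.0),
    RT: float = RT_298K,
):
    """Occupancy of each design at each REU->kcal/mol scale factor.

    Returns ``(table, rank_stable)`` where ``table`` maps design id ->
    {kappa: occupancy} and ``rank_stable`` says whether the occupancy rank
    order of the designs is identical across all kappas.
    """
    if any(k <= 0 for k in kappas):
        raise ValueError("kappas must be positive")
    table: dict[str, dict[float, float]] = {}
    orders = []
    for k in kappas:
        occs = {did: occupancy(dE, 0.0, kappa=k, RT=RT).occupancy for did, dE in designs}
        for did, o in occs.items():
            table.setdefault(did, {})[k] = o
        orders.append(tuple(sorted(occs, key=lambda d: (-occs[d], d))))
    rank_stable = all(o == orders[0] for o in orders)
    return table, rank_stable
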