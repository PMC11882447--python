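"""Deterministic synthetic fixtures with planted ground truth.

Everything here is synthetic test scaffolding, built so that the analysis
modules can be checked against analytically known answers:

* idealised seven-helix bundles with annotated static (helices 1-5) and
  switchable (helices 6-7) segments;
* water bridges planted between static and switchable residues with exact
  hydrogen-bond geometry, so the expected network counts are known by
  construction (2 edges per single-water bridge, 3 per two-water chain);
* octahedral carboxylate cages whose scorer energy minimum is at a known
  point, for exercising the two-stage ion sampler against a dense-scan
  oracle;
* activity/energy tables with a known linear relation plus Gaussian noise.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atsm import ActivityRecord, EnergyRecord
from .hbond import HBondCriteria, find_hbonds
from .ion_sampler import DefaultScorer, dense_scan
from .network import build_graph, count_static_switchable, count_water_mediated_total
from .structure_io import (
    AnnotationEntry,
    Atom,
    BWAnnotation,
    HelixSegment,
    Residue,
    StructureModel,
)


class FixtureError(RuntimeError):
    """Raised when a requested fixture geometry cannot be realised."""


# ---------------------------------------------------------------------------
# Helix bundles
# ---------------------------------------------------------------------------

_DEFAULT_CLASSES = ("static",) * 5 + ("switchable",) * 2

RISE = 1.5  # A per residue along the helix axis
TWIST = 100.0  # degrees per residue
CA_RADIUS = 2.3  # A, C-alpha distance from the helix axis


@dataclass
class BundleSpec:
    n_helices: int = 7
    bundle_radius: float = 8.5  # A, helix axes on this circle
    residues_per_helix: int = 26
    sequences: list[str] | None = None  # per-helix 1-letter strings
    class_labels: tuple[str, ...] = _DEFAULT_CLASSES
    jitter: float = 0.03  # A, coordinate noise (breaks exact degeneracies)

    def __post_init__(self) -> None:
        if len(self.class_labels) != self.n_helices:
            raise FixtureError("class_labels must cover every helix")
        if self.sequences is not None:
            if len(self.sequences) != self.n_helices or any(
                len(s) != self.residues_per_helix for s in self.sequences
            ):
                raise FixtureError("sequences must match n_helices x residues_per_helix")


_AA3 = {"A": "ALA", "S": "SER", "L": "LEU", "T": "THR", "D": "ASP", "N": "ASN"}


def _default_sequence(m: int) -> str:
    # serine at every other interior position gives the water-planting search
    # polar anchors all around the helical wheel
    seq = []
    for i in range(m):
        seq.append("S" if (2 <= i < m - 2 and i % 2 == 0) else "A")
    return "".join(seq)


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_bundle(
    spec: BundleSpec | None = None, seed: int = 0
) -> tuple[StructureModel, BWAnnotation]:
    """Build an idealised helix bundle and its annotation.

    Helices sit on a circle of ``bundle_radius``, alternating up/down, with
    1.5 A rise and 100 deg twist per residue.  Backbone N/CA/C/O plus a
    C-beta are built for every residue; serine side chains additionally get
    an OG hydroxyl oxygen extending radially from the helix axis.  Residues
    are numbered ``100 * helix + index`` on chain A, with synthetic generic
    codes ``helix.index``.
    """
    spec = spec or BundleSpec()
    rng = np.random.default_rng(seed)
    sequences = spec.sequences or [
        _default_sequence(spec.residues_per_helix) for _ in range(spec.n_helices)
    ]

    residues: list[Residue] = []
    entries: dict[tuple[str, int], AnnotationEntry] = {}
    segments: list[HelixSegment] = []
    serial = 0

    for h in range(spec.n_helices):
        helix_id = h + 1
        phi = 360.0 * h / spec.n_helices
        axis_xy = spec.bundle_radius * np.array(
            [np.cos(np.radians(phi)), np.sin(np.radians(phi)), 0.0]
        )
        direction = 1.0 if h % 2 == 0 else -1.0
        e_in = -np.array([np.cos(np.radians(phi)), np.sin(np.radians(phi)), 0.0])
        m = spec.residues_per_helix

        ca = np.zeros((m, 3))
        u_out = np.zeros((m, 3))
        for i in range(m):
            psi = direction * TWIST * i
            radial = _rot_z(psi) @ e_in
            ca[i] = axis_xy + CA_RADIUS * radial
            ca[i, 2] = direction * RISE * (i - (m - 1) / 2)
            u_out[i] = radial

        for i in range(m):
            aa = sequences[h][i]
            name = _AA3.get(aa, "ALA")
            atoms: list[Atom] = []

            def add(atom_name: str, element: str, pos: np.ndarray) -> None:
                nonlocal serial
                serial += 1
                noisy = pos + rng.normal(0.0, spec.jitter, 3)
                atoms.append(
                    Atom(serial=serial, name=atom_name, element=element, position=noisy)
                )

            prev_dir = (
                (ca[i - 1] - ca[i]) / np.linalg.norm(ca[i - 1] - ca[i])
                if i > 0
                else np.array([0.0, 0.0, -direction])
            )
            next_dir = (
                (ca[i + 1] - ca[i]) / np.linalg.norm(ca[i + 1] - ca[i])
                if i < m - 1
                else np.array([0.0, 0.0, direction])
            )
            add("N", "N", ca[i] + 1.45 * prev_dir)
            add("CA", "C", ca[i])
            c_pos = ca[i] + 1.53 * next_dir
            add("C", "C", c_pos)
            add("O", "O", c_pos + 1.23 * np.array([0.0, 0.0, direction]))
            if name != "GLY":
                cb = ca[i] + 1.53 * u_out[i]
                add("CB", "C", cb)
                if name == "SER":
                    add("OG", "O", cb + 1.40 * u_out[i])
                elif name == "THR":
                    add("OG1", "O", cb + 1.40 * u_out[i])

            resnum = 100 * helix_id + (i + 1)
            residues.append(
                Residue(chain="A", seq_number=resnum, icode="", name=name, atoms=atoms)
            )
            entries[("A", resnum)] = AnnotationEntry(
                bw_code=f"{helix_id}.{i + 1}",
                helix_id=helix_id,
                helix_class=spec.class_labels[h],
            )
        segments.append(
            HelixSegment(
                helix_id=helix_id,
                chain="A",
                start=100 * helix_id + 1,
                end=100 * helix_id + m,
                helix_class=spec.class_labels[h],
            )
        )

    model = StructureModel(model_id=f"bundle-{seed}", residues=residues)
    return model, BWAnnotation(entries, segments)


# ---------------------------------------------------------------------------
# Planted water networks
# ---------------------------------------------------------------------------

HB_IDEAL = 2.8  # A, planted water - heavy atom hydrogen-bond distance
CLEARANCE = 4.0  # A, min distance of planted waters to uninvolved polar atoms


@dataclass
class Bridge:
    kind: str  # "single" | "chain2"
    residue_a: tuple[str, int]  # static side
    residue_b: tuple[str, int]  # switchable side
    helix_a: int = 0
    helix_b: int = 0


@dataclass
class WaterNetworkSpec:
    bridges: list[Bridge]

    @property
    def expected_count(self) -> int:
        """Edges on mediating paths: 2 per single bridge, 3 per chain."""
        return sum(2 if b.kind == "single" else 3 for b in self.bridges)


@dataclass
class ExpectedNetwork:
    n_water_mediated_total: int
    n_static_switchable: int
    bridges: list[Bridge]


def _tip_atom(res: Residue) -> Atom:
    for name in ("OG", "OG1", "OD1", "OE1"):
        a = res.atom(name)
        if a is not None:
            return a
    raise FixtureError(f"residue {res.key} has no side-chain polar tip")


def _polar_positions(model: StructureModel, skip_keys: set) -> np.ndarray:
    from .hbond import collect_polar_atoms

    pts = [
        p.position
        for p in collect_polar_atoms(model)
        if p.residue.key not in skip_keys
    ]
    return np.array(pts) if pts else np.zeros((0, 3))


def _bridge_waters(
    pa: np.ndarray, pb: np.ndarray, kind: str, v: np.ndarray
) -> list[np.ndarray] | None:
    """Water position(s) at exactly HB_IDEAL from the bridged atoms, offset along v."""
    d = float(np.linalg.norm(pb - pa))
    u = (pb - pa) / d
    v = v - np.dot(v, u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        return None
    v = v / nv
    mid = (pa + pb) / 2
    if kind == "single":
        if d >= 2 * HB_IDEAL or d < 1.0:
            return None
        h = np.sqrt(HB_IDEAL**2 - (d / 2) ** 2)
        return [mid + h * v]
    # two-water chain: W1, W2 symmetric about the midpoint, HB_IDEAL apart
    half = HB_IDEAL / 2
    if abs(d / 2 - half) >= HB_IDEAL or d < 4.0:
        return None
    h = np.sqrt(HB_IDEAL**2 - (d / 2 - half) ** 2)
    return [mid - half * u + h * v, mid + half * u + h * v]


def plant_water_network(
    model: StructureModel,
    annotation: BWAnnotation,
    spec: WaterNetworkSpec,
    criteria: HBondCriteria | None = None,
) -> tuple[StructureModel, ExpectedNetwork]:
    """Plant the requested bridges as HOH oxygens; verify the network is clean.

    Single bridges place one water equidistant (2.8 A) from the two residues'
    polar tips; chains place two waters 2.8 A apart.  After planting, the
    hydrogen-bond detector is run and the water-involved edges must be exactly
    the planted ones — otherwise the geometry is rejected.
    """
    criteria = criteria or HBondCriteria()
    residues = list(model.residues)
    planted: list[np.ndarray] = []
    serial = max(a.serial for r in residues for a in r.atoms)

    for bi, bridge in enumerate(spec.bridges):
        ra = model.residue(*bridge.residue_a)
        rb = model.residue(*bridge.residue_b)
        if ra is None or rb is None:
            raise FixtureError(f"bridge residues {bridge} absent from model")
        pa, pb = _tip_atom(ra).position, _tip_atom(rb).position
        skip = {ra.key, rb.key}
        obstacles = _polar_positions(model, skip)
        placed = _place_bridge(pa, pb, bridge.kind, obstacles, planted)
        if placed is None:
            raise FixtureError(
                f"no clean geometry for bridge {bridge.residue_a}->{bridge.residue_b}"
            )
        for w in placed:
            planted.append(w)
            serial += 1
            residues.append(
                Residue(
                    chain="S",
                    seq_number=9000 + len(planted),
                    icode="",
                    name="HOH",
                    atoms=[Atom(serial=serial, name="O", element="O", position=w)],
                )
            )

    out = StructureModel(model_id=model.model_id + "+waters", residues=residues)
    expected = ExpectedNetwork(
        n_water_mediated_total=spec.expected_count,
        n_static_switchable=spec.expected_count,
        bridges=spec.bridges,
    )
    _verify_planted(out, annotation, expected, criteria)
    return out, expected


def _place_bridge(pa, pb, kind, obstacles, planted) -> list[np.ndarray] | None:
    u = pb - pa
    u = u / np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, u)) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    w1 = np.cross(u, ref)
    w1 /= np.linalg.norm(w1)
    w2 = np.cross(u, w1)
    candidates = []
    for ang in np.arange(0, 360, 30):
        a = np.radians(ang)
        candidates.append(np.cos(a) * w1 + np.sin(a) * w2)
    best, best_clear = None, -np.inf
    for v in candidates:
        waters = _bridge_waters(pa, pb, kind, v)
        if waters is None:
            return None  # distance infeasible regardless of v
        clear = np.inf
        for w in waters:
            if len(obstacles):
                clear = min(clear, float(np.linalg.norm(obstacles - w, axis=1).min()))
            for pw in planted:
                clear = min(clear, float(np.linalg.norm(pw - w)))
        if clear > best_clear:
            best, best_clear = waters, clear
    if best is None or best_clear < CLEARANCE:
        return None
    return best


def _verify_planted(model, annotation, expected: ExpectedNetwork, criteria) -> None:
    bonds = find_hbonds(model, criteria)
    graph = build_graph(model, bonds, annotation)
    total = count_water_mediated_total(graph)
    mediating = count_static_switchable(graph)
    if total != expected.n_water_mediated_total:
        raise FixtureError(
            f"planted network not clean: {total} water edges, "
            f"expected {expected.n_water_mediated_total}"
        )
    if mediating != expected.n_static_switchable:
        raise FixtureError(
            f"planted network mediating count {mediating} != "
            f"expected {expected.n_static_switchable}"
        )


def make_network_fixture(
    seed: int = 0,
    n_single: int = 3,
    n_chain2: int = 1,
    spec: BundleSpec | None = None,
) -> tuple[StructureModel, BWAnnotation, ExpectedNetwork]:
    """Bundle with planted static-switchable bridges chosen automatically.

    Searches serine pairs across static/switchable helix interfaces whose tip
    geometry admits a clean bridge of the requested kind, then plants and
    verifies.  Raises :class:`FixtureError` when the requested bridge count
    cannot be realised for this seed.
    """
    rng = np.random.default_rng(seed)
    spec = spec or BundleSpec(bundle_radius=float(rng.uniform(8.0, 9.0)))
    model, annotation = make_bundle(spec, seed=seed)

    static_sers, switch_sers = [], []
    for res in model.residues:
        if res.name != "SER":
            continue
        entry = annotation.lookup(res.chain, res.seq_number)
        if entry.helix_class == "static":
            static_sers.append(res)
        elif entry.helix_class == "switchable":
            switch_sers.append(res)

    pairs = []
    for ra in static_sers:
        for rb in switch_sers:
            d = float(np.linalg.norm(_tip_atom(ra).position - _tip_atom(rb).position))
            pairs.append((ra, rb, d))
    rng.shuffle(pairs)

    def helix_of(res):
        return annotation.lookup(res.chain, res.seq_number).helix_id

    chosen: list[Bridge] = []
    used: set = set()
    wanted = [("single", n_single), ("chain2", n_chain2)]
    for kind, count in wanted:
        lo, hi = (2.5, 2 * HB_IDEAL - 0.2) if kind == "single" else (4.5, 7.8)
        found = 0
        for ra, rb, d in pairs:
            if found >= count:
                break
            if ra.key in used or rb.key in used or not lo <= d <= hi:
                continue
            trial = chosen + [
                Bridge(kind, (ra.chain, ra.seq_number), (rb.chain, rb.seq_number),
                       helix_of(ra), helix_of(rb))
            ]
            try:
                plant_water_network(model, annotation, WaterNetworkSpec(trial))
            except FixtureError:
                continue
            chosen = trial
            used |= {ra.key, rb.key}
            found += 1
        if found < count:
            raise FixtureError(
                f"seed {seed}: only {found}/{count} clean {kind} bridges found"
            )

    planted_model, expected = plant_water_network(
        model, annotation, WaterNetworkSpec(chosen)
    )
    return planted_model, annotation, expected


# ---------------------------------------------------------------------------
# Planted ion sites
# ---------------------------------------------------------------------------


@dataclass
class IonSiteSpec:
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cage_radius: float = 2.15  # A, carboxylate oxygen distance from the center
    wall_radius: float = 4.2  # A, apolar cavity shell around the cage
    n_wall_atoms: int = 64
    jitter: float = 0.02  # A, per-atom noise


@dataclass
class IonSiteFixture:
    model: StructureModel
    true_minimum: np.ndarray
    site_center: np.ndarray
    site_residues: list[tuple[str, int]]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def plant_ion_site(
    spec: IonSiteSpec | None = None,
    seed: int = 0,
    verify: bool = True,
) -> IonSiteFixture:
    """Synthetic octahedral carboxylate cage with a known energy minimum.

    Six aspartate fragments point one carboxylate oxygen each at the cage
    center from a randomly rotated octahedral frame, all enclosed by an
    apolar cavity shell.  By symmetry the default scorer's minimum lies at
    the cage center, which is verified against a dense grid scan at
    generation time (synthetic construct, not a natural binding-site
    geometry).
    """
    spec = spec or IonSiteSpec()
    rng = np.random.default_rng(seed)
    center = np.asarray(spec.center, dtype=float)
    rot = _random_rotation(rng)
    axes = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    ) @ rot.T

    residues: list[Residue] = []
    serial = 0
    site_residues: list[tuple[str, int]] = []

    def jit(p):
        return p + rng.normal(0.0, spec.jitter, 3)

    for i, d in enumerate(axes):
        serial_base = serial
        atoms = [
            Atom(serial=serial_base + 1, name="OD1", element="O",
                 position=jit(center + spec.cage_radius * d)),
            Atom(serial=serial_base + 2, name="CG", element="C",
                 position=jit(center + (spec.cage_radius + 1.35) * d)),
            Atom(serial=serial_base + 3, name="CB", element="C",
                 position=jit(center + (spec.cage_radius + 2.65) * d)),
        ]
        serial += 3
        residues.append(
            Residue(chain="B", seq_number=10 + i, icode="", name="ASP", atoms=atoms)
        )
        site_residues.append(("B", 10 + i))
    # apolar cavity shell: dense enough that every would-be first-shell water
    # site inside the search box stays blocked once the cage is removed
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(spec.n_wall_atoms):
        z = 1.0 - 2.0 * (i + 0.5) / spec.n_wall_atoms
        r_xy = np.sqrt(max(0.0, 1.0 - z * z))
        theta = golden * i
        d = np.array([r_xy * np.cos(theta), r_xy * np.sin(theta), z]) @ rot.T
        serial += 1
        residues.append(
            Residue(
                chain="B",
                seq_number=30 + i,
                icode="",
                name="ALA",
                atoms=[
                    Atom(serial=serial, name="CB", element="C",
                         position=jit(center + spec.wall_radius * d))
                ],
            )
        )

    model = StructureModel(model_id=f"ionsite-{seed}", residues=residues)
    oxygens = np.array(
        [r.atom("OD1").position for r in residues if r.name == "ASP"]
    )
    site_center = oxygens.mean(axis=0)

    true_minimum = center
    if verify:
        pos, _ = dense_scan(
            model, site_center, DefaultScorer(), extent=2.5, spacing=0.1
        )
        if np.linalg.norm(pos - center) > 0.05:
            raise FixtureError(
                f"ion-site generation check failed: scan optimum {pos} is "
                f"{np.linalg.norm(pos - center):.3f} A from the intended center"
            )
        true_minimum = pos
    return IonSiteFixture(
        model=model,
        true_minimum=np.asarray(true_minimum, dtype=float),
        site_center=site_center,
        site_residues=site_residues,
    )


def strip_coordinating_residues(fixture: IonSiteFixture) -> StructureModel:
    """The fixture's model without its carboxylate cage (walls retained)."""
    site = set(fixture.site_residues)
    residues = [
        r for r in fixture.model.residues if (r.chain, r.seq_number) not in site
    ]
    return StructureModel(model_id=fixture.model.model_id + "-apo", residues=residues)


# ---------------------------------------------------------------------------
# Activity / energy tables
# ---------------------------------------------------------------------------


def calibrated_noise_sd(
    slope: float, ddg_range: tuple[float, float], target_abs_r: float = 0.91
) -> float:
    """Noise level giving population |Pearson r| = target for a uniform predictor."""
    if not 0 < target_abs_r < 1:
        raise ValueError("target_abs_r must be in (0,1)")
    sigma_x = (ddg_range[1] - ddg_range[0]) / np.sqrt(12.0)
    return abs(slope) * sigma_x * np.sqrt(1.0 / target_abs_r**2 - 1.0)


@dataclass
class ActivityGenSpec:
    """Generator conditions for synthetic basal-activity tables.

    Defaults describe a realistic design panel: 14 designs, conformational
    energy differences spread uniformly over [-5, 10] REU, basal activity
    declining by 0.02 (fraction of maximal agonist-induced wild-type
    activity) per REU from 0.35 at the reference, with Gaussian measurement
    noise calibrated so the population correlation magnitude is 0.91.
    """

    n_designs: int = 14
    slope: float = -0.02  # BA fraction per REU
    intercept: float = 0.35
    ddg_range: tuple[float, float] = (-5.0, 10.0)
    noise_sd: float | None = None  # None -> calibrated to |r| = 0.91
    clip: tuple[float, float] = (0.01, 0.99)

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return calibrated_noise_sd(self.slope, self.ddg_range)


def make_activity_dataset(
    spec: ActivityGenSpec | None = None, seed: int = 0
) -> tuple[list[ActivityRecord], list[EnergyRecord], dict]:
    """Paired activity/energy tables with a known linear relation.

    BA = intercept + slope * ddG_apo + N(0, noise_sd), clipped into
    ``spec.clip``; clip events are reported in the metadata dict.
    """
    spec = spec or ActivityGenSpec()
    if spec.n_designs < 3:
        raise ValueError("need at least 3 designs")
    rng = np.random.default_rng(seed)
    sd = spec.resolved_noise_sd()
    ddg = rng.uniform(*spec.ddg_range, size=spec.n_designs)
    ba_raw = spec.intercept + spec.slope * ddg + rng.normal(0.0, sd, spec.n_designs)
    ba = np.clip(ba_raw, *spec.clip)
    n_clipped = int(np.sum(ba != ba_raw))

    activities, energies = [], []
    for i in range(spec.n_designs):
        did = f"design{i + 1:02d}"
        activities.append(ActivityRecord(design_id=did, basal_activity=float(ba[i])))
        dgi = float(rng.uniform(-3.0, 3.0))
        energies.append(
            EnergyRecord(
                design_id=did,
                dG_inactive=dgi,
                dG_active=dgi + float(ddg[i]),
                ddG_apo=float(ddg[i]),
            )
        )
    meta = {
        "seed": seed,
        "noise_sd": sd,
        "n_clipped": n_clipped,
        "slope": spec.slope,
        "intercept": spec.intercept,
    }
    return activities, energies, meta
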