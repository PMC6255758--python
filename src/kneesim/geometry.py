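"""Parametric synthetic knee geometry.

Stands in for an image-segmentation pipeline: femoral condyles are
ellipsoidal articular patches, tibial plateaus are shallow spherical dishes
tessellated into poroelastic contact columns, and menisci are annular
wedge spacers on the plateau periphery that conform to the condyles.
Ligament and tendon insertion points are placed at anatomically plausible
coordinates in a tibia-fixed frame (+x anterior, +y proximal, +z lateral,
right knee, lengths in mm) and jittered per seed.

One build returns two variants sharing the tibiofemoral surfaces exactly:
Geometry A carries the patellar mechanism (patella point body, QT/PT
insertions, trochlea, MPFL/LPFL), Geometry B does not, so driving-mode
comparisons between them isolate the patellar load path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import GeometryConfig, MaterialsConfig
from .materials import SpringLigament, TrussLigament

MEDIAL, LATERAL = 0, 1


class GeometryError(ValueError):
    """Raised for non-realizable geometry configurations."""


@dataclass(frozen=True)
class Condyle:
    """Ellipsoidal femoral articular patch, femur frame."""

    center: np.ndarray  # (3,)
    semi_axes: np.ndarray  # (a_ap, b_vert, c_ml)


@dataclass(frozen=True)
class ColumnField:
    """Struct-of-arrays tessellation of the tibial/meniscal contact surface.

    All arrays have length n_columns.  ``y_top`` is the undeformed contact
    surface height; ``thickness0`` the cartilage column thickness entering
    the consolidation law; meniscal columns additionally carry a meniscus
    spacer thickness and a share of the horn-spring stiffness.
    """

    x: np.ndarray
    z: np.ndarray
    y_top: np.ndarray
    thickness0: np.ndarray
    area: np.ndarray
    normal: np.ndarray  # (n, 3) unit, roughly +y
    compartment: np.ndarray  # int, MEDIAL / LATERAL
    meniscal: np.ndarray  # bool
    meniscus_thickness: np.ndarray  # mm (0 where not meniscal)
    horn_stiffness: np.ndarray  # N/mm parallel stiffness (0 where not meniscal)

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class KneeGeometry:
    """Synthetic knee geometry (one variant)."""

    variant: str  # "A" (with patella mechanism) or "B"
    condyles: tuple[Condyle, Condyle]  # (medial, lateral)
    columns: ColumnField
    insertions: dict[str, tuple[str, np.ndarray]]  # name -> (frame, point)
    epicondyles: np.ndarray  # (2, 3) femur frame
    rp_femur: np.ndarray  # femur frame; midpoint of the epicondyles
    rp_quad: np.ndarray | None  # femur frame (variant A)
    patella_ref: np.ndarray | None  # tibia frame (variant A)
    trochlea_center: np.ndarray | None  # femur frame (variant A)
    trochlea_radius: float | None
    quad_wrap_flexion_deg: float = 15.0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def has_patella(self) -> bool:
        return self.variant == "A"


def _gaussian_bumps(rng, n, half_ap, half_ml, amplitude):
    """Smooth random thickness perturbation field over one compartment."""
    centers_x = rng.uniform(-half_ap, half_ap, n)
    centers_z = rng.uniform(-half_ml, half_ml, n)
    amps = rng.uniform(-amplitude, amplitude, n)
    widths = rng.uniform(4.0, 9.0, n)

    def f(x, z):
        out = np.zeros_like(x, dtype=float)
        for cx, cz, a, w in zip(centers_x, centers_z, amps, widths):
            out += a * np.exp(-((x - cx) ** 2 + (z - cz) ** 2) / (2 * w**2))
        return out

    return f


def ellipsoid_lower_surface(
    condyle: Condyle,
    R: np.ndarray,
    rp_ref: np.ndarray,
    rp_world: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
) -> np.ndarray:
    """Height y of the lower condyle surface above tibia-frame points (x, z)
    for a femur pose (rotation R about the femoral reference point).

    Points where the vertical line misses the ellipsoid get +inf.
    """
    c_w = rp_world + R @ (condyle.center - rp_ref)
    D = np.diag(1.0 / condyle.semi_axes**2)
    Q = R @ D @ R.T
    vx = np.asarray(x, dtype=float) - c_w[0]
    vz = np.asarray(z, dtype=float) - c_w[2]
    # quadratic in Y = y - c_w[1]: Q11 Y^2 + 2 b Y + cq = 0
    a = Q[1, 1]
    b = Q[0, 1] * vx + Q[1, 2] * vz
    cq = (
        Q[0, 0] * vx**2
        + Q[2, 2] * vz**2
        + 2.0 * Q[0, 2] * vx * vz
        - 1.0
    )
    disc = b**2 - a * cq
    y = np.full_like(vx, np.inf, dtype=float)
    hit = disc >= 0.0
    y[hit] = (-b[hit] - np.sqrt(disc[hit])) / a + c_w[1]
    return y


def build_geometry(
    geo: GeometryConfig,
    seed: int = 0,
    materials: MaterialsConfig | None = None,
) -> tuple[KneeGeometry, KneeGeometry]:
    """Generate Geometry A and Geometry B for one seed.

    Deterministic per seed.  The two variants share the tibiofemoral
    surfaces (same array objects); only the patellar mechanism differs.
    """
    rng = np.random.default_rng(seed)

    def jitter(scale, size=None):
        v = rng.uniform(-scale, scale, size)
        return v if size else float(v)

    # --- condyles -----------------------------------------------------------
    axes_nom = np.array(
        [geo.condyle_radius_ap, geo.condyle_radius_vert, geo.condyle_radius_ml]
    )
    ax_med = axes_nom * (1.0 + rng.uniform(-geo.radius_jitter, geo.radius_jitter, 3))
    ax_lat = (
        ax_med.copy()
        if geo.symmetric
        else axes_nom * (1.0 + rng.uniform(-geo.radius_jitter, geo.radius_jitter, 3))
    )

    # --- columns ------------------------------------------------------------
    s = geo.column_spacing
    a_p, b_p = geo.plateau_half_ap, geo.plateau_half_ml
    nx = int(np.floor(a_p / s))
    nz = int(np.floor(b_p / s))
    gx = np.arange(-nx, nx + 1) * s
    gz = np.arange(-nz, nz + 1) * s
    X, Z = np.meshgrid(gx, gz, indexing="ij")
    rho = np.sqrt((X / a_p) ** 2 + (Z / b_p) ** 2)
    keep = rho <= 1.0
    xs, zs, rhos = X[keep], Z[keep], rho[keep]
    n_cmp = xs.size

    thick_field = _gaussian_bumps(rng, 6, a_p, b_p, geo.thickness_jitter)
    thick_med = geo.cartilage_thickness + thick_field(xs, zs)
    if geo.symmetric:
        thick_lat = thick_med.copy()
    else:
        thick_field2 = _gaussian_bumps(rng, 6, a_p, b_p, geo.thickness_jitter)
        thick_lat = geo.cartilage_thickness + thick_field2(xs, zs)
    lo, hi = geo.thickness_band
    for th in (thick_med, thick_lat):
        np.clip(th, lo, hi, out=th)

    z_off = geo.condyle_offset_ml
    x_all = np.concatenate([xs, xs])
    z_all = np.concatenate([zs - z_off, zs + z_off])
    rho_all = np.concatenate([rhos, rhos])
    thick_all = np.concatenate([thick_med, thick_lat])
    compartment = np.concatenate(
        [np.full(n_cmp, MEDIAL), np.full(n_cmp, LATERAL)]
    )
    z_local = np.concatenate([zs, zs])

    # dished articular surface (bone follows at y_top - thickness)
    r2 = x_all**2 + z_local**2
    dish = r2 / (2.0 * geo.dish_radius)
    y_cart = geo.cartilage_thickness + dish

    # condyle centers: lowest ellipsoid point sits reference_gap above the
    # dish center of each compartment
    cy_med = ax_med[1] + geo.cartilage_thickness + geo.reference_gap
    cy_lat = ax_lat[1] + geo.cartilage_thickness + geo.reference_gap
    cond_med = Condyle(np.array([0.0, cy_med, -z_off]), ax_med)
    cond_lat = Condyle(np.array([0.0, cy_lat, z_off]), ax_lat)

    rp_femur = np.array([0.0, geo.rp_femur_height, 0.0])
    R0 = np.eye(3)

    # reference condyle height above each column (identity pose)
    y_cond = np.where(
        compartment == MEDIAL,
        ellipsoid_lower_surface(cond_med, R0, rp_femur, rp_femur, x_all, z_all),
        ellipsoid_lower_surface(cond_lat, R0, rp_femur, rp_femur, x_all, z_all),
    )

    # menisci: annular wedges conforming to the condyles; their top surface
    # closes a fixed fraction of the local ball-dish gap, so the reference
    # pose is penetration-free by construction
    meniscal = rho_all > geo.meniscus_rho
    gap_ref = y_cond - y_cart
    if np.any(gap_ref[np.isfinite(gap_ref)] < -geo.gap_tolerance):
        raise GeometryError(
            "condyle and plateau interpenetrate at the reference pose"
        )
    wedge = np.where(
        meniscal & np.isfinite(gap_ref),
        geo.meniscus_conformity * np.maximum(gap_ref, 0.0),
        0.0,
    )
    y_top = y_cart + wedge
    meniscus_thickness = np.where(
        meniscal, np.maximum(wedge, geo.meniscus_min_thickness), 0.0
    )

    # horn springs: two horns per meniscus, lumped as a parallel vertical
    # stiffness distributed uniformly over that meniscus's columns
    horn_total = None if materials is None else 2.0 * materials.horn_stiffness
    horn_stiffness = np.zeros_like(y_top)
    if horn_total is None:
        horn_total = 2.0 * 350.0
    for cmp_id in (MEDIAL, LATERAL):
        m = meniscal & (compartment == cmp_id)
        if m.any():
            horn_stiffness[m] = horn_total / m.sum()

    # outward normals of the dished surface (wedge slope folded into the
    # small-slope approximation; tangential traction stays identically zero)
    n_raw = np.stack(
        [
            -x_all / geo.dish_radius,
            np.ones_like(x_all),
            -z_local / geo.dish_radius,
        ],
        axis=1,
    )
    normal = n_raw / np.linalg.norm(n_raw, axis=1, keepdims=True)

    columns = ColumnField(
        x=x_all,
        z=z_all,
        y_top=y_top,
        thickness0=thick_all,
        area=np.full_like(y_top, s * s),
        normal=normal,
        compartment=compartment,
        meniscal=meniscal,
        meniscus_thickness=meniscus_thickness,
        horn_stiffness=horn_stiffness,
    )

    # --- insertions ---------------------------------------------------------
    half_w = geo.epicondyle_halfwidth
    epis = np.array(
        [[0.0, geo.rp_femur_height, -half_w], [0.0, geo.rp_femur_height, half_w]]
    )

    def _jit3(p, mirror_of=None):
        if geo.symmetric and mirror_of is not None:
            q = mirror_of.copy()
            q[2] = -q[2]
            return q
        return np.asarray(p, dtype=float) + jitter(geo.insertion_jitter, 3)

    insertions: dict[str, tuple[str, np.ndarray]] = {}
    fem_pts: dict[str, np.ndarray] = {}
    for name, p in geo.femur_insertions.items():
        if geo.symmetric and name == "LCL":
            pt = _jit3(p, mirror_of=fem_pts["MCL"])
        else:
            pt = _jit3(p)
        fem_pts[name] = pt
        insertions[f"{name}_femur"] = ("femur", pt)
    tib_pts: dict[str, np.ndarray] = {}
    for name, p in geo.tibia_insertions.items():
        if geo.symmetric and name == "LCL":
            pt = _jit3(p, mirror_of=tib_pts["MCL"])
        else:
            pt = _jit3(p)
        tib_pts[name] = pt
        insertions[f"{name}_tibia"] = ("tibia", pt)

    rp_quad = np.asarray(geo.rp_quad, dtype=float)
    patella_ref = np.asarray(geo.patella_ref, dtype=float)
    trochlea_center = np.asarray(geo.trochlea_center, dtype=float)
    insertions["MPFL_femur"] = ("femur", np.array([2.0, geo.rp_femur_height, -half_w]))
    insertions["LPFL_femur"] = ("femur", np.array([2.0, geo.rp_femur_height, half_w]))
    insertions["RP_Quad"] = ("femur", rp_quad)
    insertions["PT_tibia"] = ("tibia", tib_pts["PT"])

    geom_a = KneeGeometry(
        variant="A",
        condyles=(cond_med, cond_lat),
        columns=columns,
        insertions=insertions,
        epicondyles=epis,
        rp_femur=0.5 * (epis[0] + epis[1]),
        rp_quad=rp_quad,
        patella_ref=patella_ref,
        trochlea_center=trochlea_center,
        trochlea_radius=geo.trochlea_radius,
        quad_wrap_flexion_deg=geo.quad_wrap_flexion_deg,
        seed=seed,
        meta={"column_spacing": s, "symmetric": geo.symmetric},
    )
    geom_b = replace(
        geom_a,
        variant="B",
        rp_quad=None,
        patella_ref=None,
        trochlea_center=None,
        trochlea_radius=None,
    )
    return geom_a, geom_b


def attach_ligaments(
    geometry: KneeGeometry, materials: MaterialsConfig
) -> dict[str, SpringLigament | TrussLigament]:
    """Instantiate the structural elements for one geometry variant.

    Reference lengths (hence slack lengths via prestrain) are measured at
    the reference (imaging) pose.  Geometry B carries the tibiofemoral
    springs only.
    """
    elems: dict[str, SpringLigament | TrussLigament] = {}

    def _ref_len(p_fem: np.ndarray, p_tib: np.ndarray) -> float:
        return float(np.linalg.norm(p_fem - p_tib))

    for name in ("ACL", "PCL", "MCL", "LCL"):
        params = getattr(materials, name)
        p_f = geometry.insertions[f"{name}_femur"][1]
        p_t = geometry.insertions[f"{name}_tibia"][1]
        elems[name] = SpringLigament(
            name=name,
            stiffness_k=params.stiffness_k,
            prestrain=params.prestrain,
            endpoints=(f"{name}_femur", f"{name}_tibia"),
            reference_length=_ref_len(p_f, p_t),
        )

    if geometry.has_patella:
        pat = geometry.patella_ref
        elems["QT"] = SpringLigament(
            name="QT",
            stiffness_k=materials.QT.stiffness_k,
            prestrain=materials.QT.prestrain,
            endpoints=("patella", "RP_Quad"),
            reference_length=_ref_len(geometry.rp_quad, pat),
        )
        elems["PT"] = SpringLigament(
            name="PT",
            stiffness_k=materials.PT.stiffness_k,
            prestrain=materials.PT.prestrain,
            endpoints=("patella", "PT_tibia"),
            reference_length=_ref_len(geometry.insertions["PT_tibia"][1], pat),
        )
        for name in ("MPFL", "LPFL"):
            params = getattr(materials, name)
            p_f = geometry.insertions[f"{name}_femur"][1]
            elems[name] = TrussLigament(
                name=name,
                E=params.E,
                nu=params.nu,
                cross_section_area=params.area,
                endpoints=("patella", f"{name}_femur"),
                reference_length=_ref_len(p_f, pat),
            )
    return elems
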