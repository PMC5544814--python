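"""Randomized 2D head scenarios for the microwave helmet model.

The cross-section is built from concentric ellipses centred at the origin:
an outer skull ellipse (default full axes 18.2 x 14.8 cm, matching the
cranium used for the laboratory phantom), a skull shell of fixed thickness,
a CSF layer of scenario-dependent thickness, the brain, and a small interior
CSF ellipse mimicking the ventricular system.  A crescent-shaped subdural
bleeding of configurable thickness can be attached to the inner skull
boundary at one of ten angular stations (36 degrees apart).  Eight
parallel-plate waveguide ports sit on a fixed ring around the head; water
bags bridge the port apertures to the skull surface.

Five scenario parameters are randomized: head scale (+-6 % in 2 % steps),
helmet rotation (+-6 degrees, applied to the head tissues while the port
ring stays fixed), CSF layer thickness (2-5 mm), bleeding thickness
(0/0.2/0.5/1/2/2.5 cm) and bleeding position (1-10).  A ``side`` flag
mirrors the scenario about the vertical symmetry axis: the ``left`` geometry
is by construction the reflection of the ``right`` geometry with the
rotation angle negated, which is what allows left-side scattering matrices
to be obtained from right-side simulations by a port permutation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "REGIONS",
    "REGION_MATERIAL",
    "HeadModelConfig",
    "ScenarioParams",
    "ScenarioGeometry",
    "build_head_scenario",
    "crescent_region",
    "ellipse_distance",
]

#: Region labels in classification priority order (first match wins).
REGIONS = (
    "port",
    "metal",
    "water_bag",
    "skull",
    "bleeding",
    "csf",
    "csf_interior",
    "brain",
    "air",
)

#: Material assigned to each region (keys of the dielectric registry).
REGION_MATERIAL = {
    "port": "port_fill",
    "metal": "metal",
    "water_bag": "water",
    "skull": "skull",
    "bleeding": "blood",
    "csf": "csf",
    "csf_interior": "csf",
    "brain": "gray_matter",
    "air": "air",
}


@dataclass(frozen=True)
class HeadModelConfig:
    """Fixed (non-randomized) geometry of the helmet model.  Units: m, deg."""

    semi_axis_x: float = 0.091  # outer skull semi-axis along x (18.2 cm full)
    semi_axis_y: float = 0.074  # outer skull semi-axis along y (14.8 cm full)
    skull_thickness: float = 0.007
    interior_csf_semi: tuple[float, float] = (0.015, 0.0075)
    head_scales: tuple[float, ...] = (0.94, 0.96, 0.98, 1.00, 1.02, 1.04, 1.06)
    rotation_max_deg: float = 6.0
    csf_range: tuple[float, float] = (0.002, 0.005)
    class_thicknesses: tuple[float, ...] = (0.0, 0.002, 0.005, 0.010, 0.020, 0.025)
    n_positions: int = 10
    # crescent angular half-width (deg): ref value at ref thickness plus slope;
    # 18 deg at 0.5 cm makes adjacent 36-deg stations overlap exactly for
    # thicknesses above 0.5 cm.
    crescent_halfwidth_ref_deg: float = 18.0
    crescent_ref_thickness: float = 0.005
    crescent_halfwidth_slope_deg_per_m: float = 600.0
    # port ring
    n_ports: int = 8
    port_radius: float = 0.105  # radial position of the apertures
    port_length: float = 0.030  # waveguide stub length (aperture -> port plane)
    aperture_width: float = 0.025
    wall_thickness: float = 0.004
    port_eps: float = 20.0
    # water bags (trapezoidal patch from aperture towards the skull)
    water_bags: bool = True
    bag_width_at_aperture: float = 0.025
    bag_width_inner: float = 0.040
    bag_width_inner_radius: float = 0.060
    bag_min_radius: float = 0.050

    @property
    def boundary_radius(self) -> float:
        """Radius of the circular outer truncation boundary (port planes lie on it)."""
        return self.port_radius + self.port_length

    @property
    def port_angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_ports) / self.n_ports

    def crescent_halfwidth_rad(self, thickness: float) -> float:
        deg = self.crescent_halfwidth_ref_deg + self.crescent_halfwidth_slope_deg_per_m * (
            thickness - self.crescent_ref_thickness
        )
        return math.radians(min(max(deg, 1.0), 90.0))

    def mirror_permutation(self) -> np.ndarray:
        """Port index permutation under reflection about the y-axis (involution)."""
        n = self.n_ports
        return (n // 2 - np.arange(n)) % n


@dataclass(frozen=True)
class ScenarioParams:
    """The five randomized parameters of one simulated "patient"."""

    head_scale: float = 1.0
    rotation_deg: float = 0.0
    csf_thickness: float = 0.0035
    bleeding_thickness: float = 0.0
    position_index: int = 1  # 1..10, ignored when bleeding_thickness == 0
    side: str = "right"
    rng_seed: int = 0

    def validate(self, config: HeadModelConfig) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if not any(
            math.isclose(self.bleeding_thickness, t, abs_tol=1e-12)
            for t in config.class_thicknesses
        ):
            raise ValueError(
                f"bleeding_thickness {self.bleeding_thickness} not in configured class set"
            )
        if self.bleeding_thickness > 0 and not (
            1 <= self.position_index <= config.n_positions
        ):
            raise ValueError("position_index out of range")
        lo, hi = config.csf_range
        if not (lo - 1e-12 <= self.csf_thickness <= hi + 1e-12):
            raise ValueError("csf_thickness outside configured range")
        if abs(self.rotation_deg) > config.rotation_max_deg + 1e-9:
            raise ValueError("rotation_deg outside configured bound")
        if self.head_scale <= 0:
            raise ValueError("head_scale must be positive")


# --------------------------------------------------------------------------
# ellipse helpers
# --------------------------------------------------------------------------

def _ellipse_polar_radius(a: float, b: float, theta) -> np.ndarray:
    """Radius of the ellipse boundary along polar angle theta."""
    c, s = np.cos(theta), np.sin(theta)
    return a * b / np.sqrt((b * c) ** 2 + (a * s) ** 2)


def ellipse_distance(points: np.ndarray, a: float, b: float) -> np.ndarray:
    """Unsigned Euclidean distance from ``points`` (N,2) to the ellipse boundary.

    Newton iteration on the parametric angle for the foot-point condition;
    accurate for points within a few semi-axes of the boundary (which is where
    it is used: crescent depth relative to the inner skull surface).
    """
    p = np.abs(np.asarray(points, dtype=float).reshape(-1, 2))
    px, py = p[:, 0], p[:, 1]
    t = np.arctan2(a * py, b * px)  # good initial guess
    a2b2 = a * a - b * b
    for _ in range(12):
        ct, st = np.cos(t), np.sin(t)
        f = a2b2 * ct * st - px * a * st + py * b * ct
        df = a2b2 * (ct * ct - st * st) - px * a * ct - py * b * st
        step = f / np.where(np.abs(df) > 1e-300, df, 1e-300)
        t = np.clip(t - step, 0.0, np.pi / 2)
    return np.hypot(px - a * np.cos(t), py - b * np.sin(t))


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    return (theta + np.pi) % (2.0 * np.pi) - np.pi


# --------------------------------------------------------------------------
# scenario geometry
# --------------------------------------------------------------------------

class ScenarioGeometry:
    """Region map of one head scenario.

    Exposes a vectorized point classifier (``classify``), interface polylines
    for mesh generation, and the derived ellipse parameters.  All tissue
    ellipses live in the *head frame*; the port ring lives in the fixed *lab
    frame*.  The head frame is obtained from the lab frame by (optionally)
    reflecting about the y-axis for left-side scenarios and rotating by the
    helmet rotation angle.
    """

    def __init__(self, params: ScenarioParams, config: HeadModelConfig | None = None):
        config = config if config is not None else HeadModelConfig()
        params.validate(config)
        self.params = params
        self.config = config

        s = params.head_scale
        self.a_outer = config.semi_axis_x * s
        self.b_outer = config.semi_axis_y * s
        self.a_inner = self.a_outer - config.skull_thickness
        self.b_inner = self.b_outer - config.skull_thickness
        self.a_brain = self.a_inner - params.csf_thickness
        self.b_brain = self.b_inner - params.csf_thickness
        if min(self.a_brain, self.b_brain) <= 0 or params.bleeding_thickness >= min(
            self.a_inner, self.b_inner
        ):
            raise ValueError("bleeding thicker than brain semi-axis")
        # effective rotation applied in the head frame; 'left' reflects x
        self._reflect = params.side == "left"
        self._rot = math.radians(-params.rotation_deg if self._reflect else params.rotation_deg)
        self._station = (
            2.0 * np.pi * (params.position_index - 1) / config.n_positions
        )
        self._halfwidth = config.crescent_halfwidth_rad(params.bleeding_thickness)
        # sanity: aperture ring must clear the largest head
        if config.port_radius <= self.a_outer:
            raise ValueError("port aperture ring intersects the head")
        # ports must not overlap around the ring
        pitch = 2.0 * np.pi * config.port_radius / config.n_ports
        if config.aperture_width + 2 * config.wall_thickness >= pitch:
            raise ValueError("overlapping ports: aperture+walls exceed ring pitch")

    # -- frames ------------------------------------------------------------

    def to_head_frame(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float).reshape(-1, 2).copy()
        if self._reflect:
            p[:, 0] = -p[:, 0]
        c, s = math.cos(-self._rot), math.sin(-self._rot)
        q = np.empty_like(p)
        q[:, 0] = c * p[:, 0] - s * p[:, 1]
        q[:, 1] = s * p[:, 0] + c * p[:, 1]
        return q

    def to_lab_frame(self, points: np.ndarray) -> np.ndarray:
        q = np.asarray(points, dtype=float).reshape(-1, 2)
        c, s = math.cos(self._rot), math.sin(self._rot)
        p = np.empty_like(q)
        p[:, 0] = c * q[:, 0] - s * q[:, 1]
        p[:, 1] = s * q[:, 0] + c * q[:, 1]
        if self._reflect:
            p = p.copy()
            p[:, 0] = -p[:, 0]
        return p

    # -- crescent ----------------------------------------------------------

    def crescent_depth(self, theta_head) -> np.ndarray:
        """Lesion depth profile d(theta) measured inward from the inner skull."""
        t = self.params.bleeding_thickness
        if t <= 0:
            return np.zeros(np.shape(theta_head))
        dtheta = _wrap_angle(np.asarray(theta_head) - self._station)
        inside = np.abs(dtheta) < self._halfwidth
        prof = np.cos(np.pi * dtheta / (2.0 * self._halfwidth)) ** 2
        return np.where(inside, t * prof, 0.0)

    def _bleeding_mask(self, q: np.ndarray, rho_inner: np.ndarray) -> np.ndarray:
        if self.params.bleeding_thickness <= 0:
            return np.zeros(len(q), dtype=bool)
        theta = np.arctan2(q[:, 1], q[:, 0])
        d = self.crescent_depth(theta)
        cand = (rho_inner <= 1.0) & (d > 0)
        out = np.zeros(len(q), dtype=bool)
        if np.any(cand):
            dist = ellipse_distance(q[cand], self.a_inner, self.b_inner)
            out[cand] = dist <= d[cand]
        return out

    # -- ports / bags (lab frame) -------------------------------------------

    def _port_uv(self, points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        phi = self.config.port_angles[k]
        c, s = math.cos(phi), math.sin(phi)
        u = points[:, 0] * c + points[:, 1] * s
        v = -points[:, 0] * s + points[:, 1] * c
        return u, v

    def _bag_halfwidth(self, u: np.ndarray) -> np.ndarray:
        cfg = self.config
        frac = np.clip(
            (cfg.port_radius - u) / (cfg.port_radius - cfg.bag_width_inner_radius),
            0.0,
            1.0,
        )
        return 0.5 * (cfg.bag_width_at_aperture + frac * (cfg.bag_width_inner - cfg.bag_width_at_aperture))

    # -- classification ------------------------------------------------------

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Region index (into :data:`REGIONS`) for each point (N,2), lab frame."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        n = len(pts)
        cfg = self.config
        out = np.full(n, REGIONS.index("air"), dtype=np.int8)

        q = self.to_head_frame(pts)
        rho_outer = (q[:, 0] / self.a_outer) ** 2 + (q[:, 1] / self.b_outer) ** 2
        rho_inner = (q[:, 0] / self.a_inner) ** 2 + (q[:, 1] / self.b_inner) ** 2
        rho_brain = (q[:, 0] / self.a_brain) ** 2 + (q[:, 1] / self.b_brain) ** 2
        in_head = rho_outer <= 1.0

        # tissues (lowest priority first, later assignments overwrite)
        brain = rho_brain <= 1.0
        out[brain] = REGIONS.index("brain")
        ia, ib = cfg.interior_csf_semi
        ivent = (q[:, 0] / ia) ** 2 + (q[:, 1] / ib) ** 2 <= 1.0
        out[brain & ivent] = REGIONS.index("csf_interior")
        csf = (rho_inner <= 1.0) & ~brain
        out[csf] = REGIONS.index("csf")
        bleed = self._bleeding_mask(q, rho_inner)
        out[bleed] = REGIONS.index("bleeding")
        out[in_head & (rho_inner > 1.0)] = REGIONS.index("skull")

        # helmet structures (highest priority), lab frame
        r_ap, r_b = cfg.port_radius, self.config.boundary_radius
        half_w = 0.5 * cfg.aperture_width
        for k in range(cfg.n_ports):
            u, v = self._port_uv(pts, k)
            av = np.abs(v)
            stub = (u >= r_ap) & (u <= r_b + 1e-9) & (av <= half_w)
            wall = (
                (u >= r_ap - cfg.wall_thickness)
                & (u <= r_b + 1e-9)
                & (av > half_w)
                & (av <= half_w + cfg.wall_thickness)
            )
            out[stub & ~in_head] = REGIONS.index("port")
            out[wall & ~in_head] = REGIONS.index("metal")
            if cfg.water_bags:
                bag = (
                    ~in_head
                    & (u >= cfg.bag_min_radius)
                    & (u < r_ap)
                    & (av <= self._bag_halfwidth(u))
                )
                keep = bag & ~np.isin(
                    out, [REGIONS.index("port"), REGIONS.index("metal")]
                )
                out[keep] = REGIONS.index("water_bag")
        return out

    def region_name(self, idx) -> np.ndarray:
        return np.asarray(REGIONS, dtype=object)[idx]

    # -- interface polylines (for meshing) ------------------------------------

    def _ellipse_ring(self, a: float, b: float, spacing: float) -> np.ndarray:
        perim = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
        npts = max(16, int(math.ceil(perim / spacing)))
        npts += npts % 2  # even count keeps the ring mirror-symmetric
        t = 2.0 * np.pi * np.arange(npts) / npts
        return np.column_stack([a * np.cos(t), b * np.sin(t)])

    def interface_points(self, h_of_region: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
        """Points along all material interfaces, with per-point target spacing.

        ``h_of_region`` maps region name -> local target element size.  Returns
        ``(points (K,2) lab frame, spacing (K,))``.
        """
        cfg = self.config
        h = h_of_region
        pts_list: list[np.ndarray] = []
        sp_list: list[np.ndarray] = []

        def add(points: np.ndarray, spacing: float) -> None:
            if len(points):
                pts_list.append(points)
                sp_list.append(np.full(len(points), spacing))

        # tissue ellipses (head frame -> lab)
        h_sk = min(h["skull"], h["water_bag"], h["air"])
        add(self.to_lab_frame(self._ellipse_ring(self.a_outer, self.b_outer, h_sk)), h_sk)
        h_ic = min(h["skull"], h["csf"], h["bleeding"])
        add(self.to_lab_frame(self._ellipse_ring(self.a_inner, self.b_inner, h_ic)), h_ic)
        h_br = min(h["csf"], h["brain"])
        add(self.to_lab_frame(self._ellipse_ring(self.a_brain, self.b_brain, h_br)), h_br)
        ia, ib = cfg.interior_csf_semi
        h_iv = min(h["csf_interior"], h["brain"])
        add(self.to_lab_frame(self._ellipse_ring(ia, ib, h_iv)), h_iv)

        # crescent inner edge
        t_bl = self.params.bleeding_thickness
        if t_bl > 0:
            h_bl = min(h["bleeding"], h["brain"], h["csf"])
            arc = self._halfwidth * _ellipse_polar_radius(
                self.a_inner, self.b_inner, self._station
            ) * 2.0
            nb = max(8, int(math.ceil(arc / h_bl)))
            th = self._station + np.linspace(-self._halfwidth, self._halfwidth, nb)
            r = _ellipse_polar_radius(self.a_inner, self.b_inner, th)
            bpts = np.column_stack([r * np.cos(th), r * np.sin(th)])
            # inward normal of the ellipse at the boundary point
            nx = bpts[:, 0] / self.a_inner**2
            ny = bpts[:, 1] / self.b_inner**2
            nn = np.hypot(nx, ny)
            d = self.crescent_depth(th)
            inner = bpts - np.column_stack([nx / nn, ny / nn]) * d[:, None]
            add(self.to_lab_frame(inner), h_bl)

        # port stubs and walls (lab frame)
        r_ap, r_b = cfg.port_radius, cfg.boundary_radius
        half_w = 0.5 * cfg.aperture_width
        h_p = min(h["port"], h["air"])
        h_m = min(h["metal"], h["air"], h["port"])
        for k in range(cfg.n_ports):
            phi = cfg.port_angles[k]
            c, s = math.cos(phi), math.sin(phi)

            def seg(u0, v0, u1, v1, spacing):
                length = math.hypot(u1 - u0, v1 - v0)
                npts = max(2, int(math.ceil(length / spacing)) + 1)
                uu = np.linspace(u0, u1, npts)
                vv = np.linspace(v0, v1, npts)
                return np.column_stack([uu * c - vv * s, uu * s + vv * c])

            # inner guide walls (port/metal interface)
            add(seg(r_ap, -half_w, r_b, -half_w, h_p)[:-1], h_p)
            add(seg(r_ap, half_w, r_b, half_w, h_p)[:-1], h_p)
            # outer wall faces (metal/air)
            wo = half_w + cfg.wall_thickness
            add(seg(r_ap - cfg.wall_thickness, -wo, r_b, -wo, h_m)[:-1], h_m)
            add(seg(r_ap - cfg.wall_thickness, wo, r_b, wo, h_m)[:-1], h_m)
            # wall front faces at the aperture plane
            add(seg(r_ap - cfg.wall_thickness, half_w, r_ap - cfg.wall_thickness, wo, h_m), h_m)
            add(seg(r_ap - cfg.wall_thickness, -wo, r_ap - cfg.wall_thickness, -half_w, h_m), h_m)
            # aperture line (port/water-bag interface)
            add(seg(r_ap, -half_w, r_ap, half_w, h_p), h_p)

            if cfg.water_bags:
                h_b = min(h["water_bag"], h["air"])
                uu = np.arange(cfg.bag_min_radius, r_ap, h_b)
                if len(uu):
                    hw = self._bag_halfwidth(uu)
                    for sgn in (-1.0, 1.0):
                        vv = sgn * hw
                        pts = np.column_stack([uu * c - vv * s, uu * s + vv * c])
                        add(pts, h_b)

        return np.vstack(pts_list), np.concatenate(sp_list)

    # -- misc ------------------------------------------------------------------

    def mirrored(self) -> "ScenarioGeometry":
        """Geometry of the scenario reflected about the vertical symmetry axis."""
        p = self.params
        return ScenarioGeometry(
            replace(
                p,
                side="left" if p.side == "right" else "right",
                rotation_deg=-p.rotation_deg,
            ),
            self.config,
        )

    def to_json(self) -> str:
        d = {
            "params": self.params.__dict__,
            "config": {k: v for k, v in self.config.__dict__.items()},
        }
        return json.dumps(d, default=lambda o: list(o) if isinstance(o, tuple) else o)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioGeometry":
        d = json.loads(text)
        params = ScenarioParams(**d["params"])
        cfg_kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in d["config"].items()
        }
        return cls(params, HeadModelConfig(**cfg_kwargs))


def build_head_scenario(
    params: ScenarioParams, config: HeadModelConfig | None = None
) -> ScenarioGeometry:
    """Construct the region map of one randomized head scenario."""
    return ScenarioGeometry(params, config)


def crescent_region(
    thickness: float,
    position_index: int,
    side: str,
    head: ScenarioGeometry,
) -> Callable[[np.ndarray], np.ndarray]:
    """Stand-alone crescent classifier attached to ``head``'s inner skull boundary.

    Returns a boolean point-membership function (lab frame).  Useful for
    overlap/depth diagnostics independent of the full region map.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if not (1 <= position_index <= head.config.n_positions):
        raise ValueError("position_index out of range")
    geom = ScenarioGeometry(
        replace(
            head.params,
            bleeding_thickness=thickness,
            position_index=position_index,
            side=side,
        ),
        head.config,
    )

    def member(points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        q = geom.to_head_frame(pts)
        rho = (q[:, 0] / geom.a_inner) ** 2 + (q[:, 1] / geom.b_inner) ** 2
        return geom._bleeding_mask(q, rho)

    return member
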