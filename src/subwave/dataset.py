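"""Labeled datasets of simulated helmet measurements.

Sampling follows the study design: six classes (no bleeding plus crescent
bleedings of 0.2/0.5/1/2/2.5 cm), bleeding positions and sides balanced
within each class, seven head sizes (+-6 % in 2 % steps), CSF layer
thickness uniform in 2-5 mm and helmet rotation uniform in +-6 degrees.
Left-side lesions are obtained from right-side solves through the port
reflection permutation, mirroring how the study reused right-side
simulations.

Each observation's scattering matrices are flattened into one complex
feature vector: the unique channels (i, j) with j >= i (reciprocity makes
j < i redundant), in the canonical order (1,1), (1,2), ..., (1,n), (2,2),
..., (n,n), each channel contributing all frequencies contiguously.  No
further preprocessing (no scaling, no detrending) is applied; additive
complex white Gaussian noise is available as an explicit option, default
off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np

from .dielectrics import MaterialSet
from .fem import SParameterSet, mirror_sparams, sweep_scenario
from .geometry import HeadModelConfig, ScenarioGeometry, ScenarioParams

__all__ = [
    "FeatureVector",
    "LabeledDataset",
    "DatasetBuildError",
    "sample_scenarios",
    "featurize",
    "build_dataset",
    "build_validation_dataset",
    "validation_thicknesses",
    "validation_head_scales",
    "channel_order",
    "class_names_for",
]


class DatasetBuildError(RuntimeError):
    pass


def channel_order(n_ports: int) -> list[tuple[int, int]]:
    """Canonical (i, j) channel order, 1-based, j >= i."""
    return [(i, j) for i in range(1, n_ports + 1) for j in range(i, n_ports + 1)]


def class_names_for(thicknesses: Sequence[float]) -> list[str]:
    names = []
    for t in thicknesses:
        names.append("no_bleeding" if t == 0 else f"{t*100:g}cm")
    return names


@dataclass
class FeatureVector:
    """One observation: concatenated complex channels of an S-parameter sweep."""

    values: np.ndarray  # complex, length n(n+1)/2 * F
    channels: list[tuple[int, int]]  # 1-based (i, j), j >= i
    frequencies: np.ndarray
    label: int | None = None
    group_id: int | None = None
    params: ScenarioParams | None = None

    def __post_init__(self) -> None:
        expected = len(self.channels) * len(self.frequencies)
        if len(self.values) != expected:
            raise ValueError(f"feature length {len(self.values)} != {expected}")

    @property
    def channel_index_map(self) -> list[tuple[int, int, float]]:
        """Ordered (i, j, frequency) per element."""
        return [
            (i, j, float(f))
            for (i, j) in self.channels
            for f in self.frequencies
        ]


def featurize(sps: SParameterSet, reciprocity_tol: float = 1e-6) -> FeatureVector:
    """Flatten an S-parameter sweep into the canonical complex feature vector."""
    if not np.all(np.isfinite(sps.s)):
        raise ValueError("NaN/inf in S-parameters")
    if sps.reciprocity_error() > reciprocity_tol:
        raise ValueError("S-parameter set violates reciprocity")
    n = sps.n_ports
    chans = channel_order(n)
    blocks = [sps.s[:, i - 1, j - 1] for (i, j) in chans]
    return FeatureVector(
        values=np.concatenate(blocks),
        channels=chans,
        frequencies=sps.frequencies,
        params=sps.params,
    )


@dataclass
class LabeledDataset:
    """Class-labeled collection of feature vectors (rows of ``X``)."""

    X: np.ndarray  # (N, D) complex
    y: np.ndarray  # (N,) int class indices into class_names
    groups: np.ndarray  # (N,) replicate-group ids
    class_names: list[str]
    channels: list[tuple[int, int]]
    frequencies: np.ndarray
    scenario_params: list[ScenarioParams] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=complex)
        self.y = np.asarray(self.y, dtype=int)
        self.groups = np.asarray(self.groups, dtype=int)
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y, groups must have equal length")
        if len(self.y) and not (0 <= self.y.min() and self.y.max() < len(self.class_names)):
            raise ValueError("labels out of range")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        sp = (
            [self.scenario_params[i] for i in idx]
            if self.scenario_params is not None
            else None
        )
        return LabeledDataset(
            self.X[idx], self.y[idx], self.groups[idx],
            list(self.class_names), list(self.channels), self.frequencies,
            scenario_params=sp, provenance=dict(self.provenance),
        )

    # -- persistence --------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=self.X)
            f.create_dataset("labels", data=self.y)
            f.create_dataset("groups", data=self.groups)
            f.create_dataset("frequencies", data=self.frequencies)
            f.create_dataset("channel_i", data=np.array([c[0] for c in self.channels]))
            f.create_dataset("channel_j", data=np.array([c[1] for c in self.channels]))
            f.attrs["class_names"] = json.dumps(self.class_names)
            f.attrs["provenance"] = json.dumps(self.provenance, default=str)
            if self.scenario_params is not None:
                f.attrs["scenario_params"] = json.dumps(
                    [p.__dict__ for p in self.scenario_params]
                )

    @classmethod
    def from_hdf5(cls, path) -> "LabeledDataset":
        with h5py.File(path, "r") as f:
            ci = f["channel_i"][:]
            cj = f["channel_j"][:]
            params = None
            if "scenario_params" in f.attrs:
                params = [
                    ScenarioParams(**d) for d in json.loads(f.attrs["scenario_params"])
                ]
            return cls(
                X=f["features"][:],
                y=f["labels"][:],
                groups=f["groups"][:],
                class_names=json.loads(f.attrs["class_names"]),
                channels=[(int(a), int(b)) for a, b in zip(ci, cj)],
                frequencies=f["frequencies"][:],
                scenario_params=params,
                provenance=json.loads(f.attrs["provenance"]),
            )


# --------------------------------------------------------------------------
# scenario sampling
# --------------------------------------------------------------------------

def _balanced_choice(values: Sequence, n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws with per-value counts differing by at most 1, in random order."""
    values = list(values)
    k = len(values)
    reps = n // k
    base = np.repeat(np.arange(k), reps)
    extra = rng.choice(k, size=n - reps * k, replace=False)
    idx = np.concatenate([base, extra]).astype(int)
    rng.shuffle(idx)
    return np.asarray(values, dtype=object)[idx]


def sample_scenarios(
    n_per_class: int,
    class_thicknesses: Sequence[float] | None = None,
    config: HeadModelConfig | None = None,
    seed: int = 0,
    head_scales: Sequence[float] | None = None,
) -> list[ScenarioParams]:
    """Randomized scenario parameters with the study's class structure.

    Within each class, bleeding positions, sides and head sizes are balanced
    (per-stratum counts differ by at most 1); CSF thickness and helmet
    rotation are uniform.  Deterministic under ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    cfg = config if config is not None else HeadModelConfig()
    thicknesses = (
        tuple(class_thicknesses) if class_thicknesses is not None else cfg.class_thicknesses
    )
    scales = tuple(head_scales) if head_scales is not None else cfg.head_scales
    rng = np.random.default_rng(seed)
    lo, hi = cfg.csf_range
    out: list[ScenarioParams] = []
    for t in thicknesses:
        scale_draw = _balanced_choice(scales, n_per_class, rng)
        if t > 0:
            pos_draw = _balanced_choice(range(1, cfg.n_positions + 1), n_per_class, rng)
            side_draw = _balanced_choice(["right", "left"], n_per_class, rng)
        else:
            pos_draw = np.full(n_per_class, 1, dtype=object)
            side_draw = np.full(n_per_class, "right", dtype=object)
        csf = rng.uniform(lo, hi, size=n_per_class)
        rot = rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg, size=n_per_class)
        for i in range(n_per_class):
            out.append(
                ScenarioParams(
                    head_scale=float(scale_draw[i]),
                    rotation_deg=float(rot[i]),
                    csf_thickness=float(csf[i]),
                    bleeding_thickness=float(t),
                    position_index=int(pos_draw[i]),
                    side=str(side_draw[i]),
                    rng_seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return out


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def _label_for(thickness: float, thicknesses: Sequence[float]) -> int:
    for k, t in enumerate(thicknesses):
        if abs(thickness - t) < 1e-12:
            return k
    raise DatasetBuildError(f"thickness {thickness} matches no class")


def build_dataset(
    scenarios: Sequence[ScenarioParams],
    frequencies: np.ndarray,
    config: HeadModelConfig | None = None,
    materials: MaterialSet | None = None,
    class_thicknesses: Sequence[float] | None = None,
    elements_per_wavelength: int = 8,
    noise_std: float = 0.0,
    noise_seed: int = 0,
    progress: bool = False,
) -> LabeledDataset:
    """Run the solver for every scenario and assemble labeled feature vectors.

    Left-side lesions are simulated as their mirrored right-side counterparts
    and mapped back through the port reflection permutation.  Optional
    additive complex white Gaussian noise models the measurement-noise term of
    the signal model (default off: the simulation pipeline is deterministic).
    """
    cfg = config if config is not None else HeadModelConfig()
    ms = materials if materials is not None else MaterialSet()
    thicknesses = (
        tuple(class_thicknesses) if class_thicknesses is not None else cfg.class_thicknesses
    )
    names = class_names_for(thicknesses)
    perm = cfg.mirror_permutation()

    iterator = enumerate(scenarios)
    if progress:
        try:
            from tqdm import tqdm

            iterator = enumerate(tqdm(scenarios, desc="scenarios"))
        except ImportError:  # pragma: no cover
            pass

    rows, labels, groups, used_params = [], [], [], []
    failures: list[tuple[int, str]] = []
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    for gid, params in iterator:
        try:
            if params.side == "left":
                right = replace(
                    params, side="right", rotation_deg=-params.rotation_deg
                )
                sps = sweep_scenario(
                    ScenarioGeometry(right, cfg), freqs, ms,
                    elements_per_wavelength=elements_per_wavelength,
                )
                sps = mirror_sparams(sps, perm)
            else:
                sps = sweep_scenario(
                    ScenarioGeometry(params, cfg), freqs, ms,
                    elements_per_wavelength=elements_per_wavelength,
                )
            fv = featurize(sps)
        except Exception as exc:
            failures.append((gid, str(exc)))
            continue
        rows.append(fv.values)
        labels.append(_label_for(params.bleeding_thickness, thicknesses))
        groups.append(gid)
        used_params.append(params)

    if failures:
        raise DatasetBuildError(
            f"{len(failures)}/{len(scenarios)} scenarios failed; first: {failures[0]}"
        )

    X = np.asarray(rows, dtype=complex)
    if noise_std > 0:
        nrng = np.random.default_rng(noise_seed)
        X = X + noise_std * (
            nrng.standard_normal(X.shape) + 1j * nrng.standard_normal(X.shape)
        ) / np.sqrt(2.0)

    return LabeledDataset(
        X=X,
        y=np.asarray(labels),
        groups=np.asarray(groups),
        class_names=names,
        channels=channel_order(cfg.n_ports),
        frequencies=freqs,
        scenario_params=used_params,
        provenance={
            "n_scenarios": len(scenarios),
            "elements_per_wavelength": elements_per_wavelength,
            "noise_std": noise_std,
            "class_thicknesses": list(thicknesses),
        },
    )


#: Validation-set parameter values: off-grid midpoints of the training ranges.
def validation_thicknesses() -> tuple[float, ...]:
    return (0.0035, 0.0075, 0.015, 0.0225)


def validation_head_scales() -> tuple[float, ...]:
    return (0.95, 0.97, 0.99, 1.01, 1.03, 1.05)


def build_validation_dataset(
    config: HeadModelConfig | None = None,
    seed: int = 1,
    n_no_bleeding: int = 250,
    n_per_bleeding_class: int | None = None,
    thicknesses: Sequence[float] | None = None,
    head_scales: Sequence[float] | None = None,
    frequencies: np.ndarray | None = None,
    materials: MaterialSet | None = None,
    elements_per_wavelength: int = 8,
    progress: bool = False,
) -> LabeledDataset:
    """Dataset with *different* bleeding/head-size values spanning the same ranges.

    Default class sizes mirror the study's validation design (250 no-bleeding
    observations and 1250 bleeding observations split over four off-grid
    thicknesses).  Raises if any validation value coincides with a training
    value.
    """
    cfg = config if config is not None else HeadModelConfig()
    th = tuple(thicknesses) if thicknesses is not None else validation_thicknesses()
    hs = tuple(head_scales) if head_scales is not None else validation_head_scales()
    if n_per_bleeding_class is not None:
        per_class = [n_per_bleeding_class] * len(th)
    else:
        # split the study's 1250 bleeding observations over the thicknesses
        base, rem = divmod(1250, len(th))
        per_class = [base + (1 if i < rem else 0) for i in range(len(th))]
    for t in th:
        if any(abs(t - tt) < 1e-12 for tt in cfg.class_thicknesses):
            raise ValueError(f"validation thickness {t} overlaps a training value")
        if not (min(cfg.class_thicknesses) < t < max(cfg.class_thicknesses)):
            raise ValueError(f"validation thickness {t} outside training range")
    for s in hs:
        if any(abs(s - ss) < 1e-12 for ss in cfg.head_scales):
            raise ValueError(f"validation head scale {s} overlaps a training value")
        if not (min(cfg.head_scales) <= s <= max(cfg.head_scales)):
            raise ValueError(f"validation head scale {s} outside training range")

    val_classes = (0.0,) + th
    val_cfg = replace(cfg, class_thicknesses=val_classes, head_scales=hs)
    rng = np.random.default_rng(seed)
    scen_nb = sample_scenarios(
        n_no_bleeding, (0.0,), val_cfg, seed=int(rng.integers(0, 2**31 - 1))
    )
    scen_bl: list[ScenarioParams] = []
    for t, n_t in zip(th, per_class):
        scen_bl += sample_scenarios(
            n_t, (t,), val_cfg, seed=int(rng.integers(0, 2**31 - 1))
        )
    freqs = (
        np.atleast_1d(np.asarray(frequencies, dtype=float))
        if frequencies is not None
        else None
    )
    if freqs is None:
        from .fem import default_frequency_grid

        freqs = default_frequency_grid()
    ds = build_dataset(
        scen_nb + scen_bl, freqs, val_cfg, materials,
        class_thicknesses=val_classes,
        elements_per_wavelength=elements_per_wavelength,
        progress=progress,
    )
    ds.provenance["role"] = "validation"
    return ds


# --------------------------------------------------------------------------
# measured-data import
# --------------------------------------------------------------------------

def dataset_from_touchstone(
    files: Sequence,
    labels: Sequence[int],
    class_names: Sequence[str],
    groups: Sequence[int] | None = None,
    reciprocity_tol: float = 0.05,
) -> LabeledDataset:
    """Build a labeled dataset from measured multiport Touchstone files.

    One file per observation, with user-supplied class labels and replicate
    group ids (measurements taken without repositioning the helmet share a
    group).  Measured S matrices are symmetrized (reciprocity holds only
    within instrument accuracy, hence the loose default tolerance); all
    files must share the frequency grid and port count.
    """
    from .touchstone import read_touchstone

    if len(files) != len(labels):
        raise ValueError("files and labels must have equal length")
    if groups is None:
        groups = np.arange(len(files))
    rows, freqs_ref, chans = [], None, None
    for path in files:
        f, s = read_touchstone(path)
        sps = SParameterSet(f, s).symmetrized()
        if freqs_ref is None:
            freqs_ref = sps.frequencies
            chans = channel_order(sps.n_ports)
        elif len(sps.frequencies) != len(freqs_ref) or not np.allclose(
            sps.frequencies, freqs_ref
        ):
            raise ValueError(f"{path}: frequency grid differs from the first file")
        rows.append(featurize(sps, reciprocity_tol=reciprocity_tol).values)
    return LabeledDataset(
        X=np.asarray(rows), y=np.asarray(labels, dtype=int),
        groups=np.asarray(groups, dtype=int), class_names=list(class_names),
        channels=chans, frequencies=freqs_ref,
        provenance={"role": "measured", "n_files": len(files)},
    )


def dataset_from_manifest(manifest_csv, class_names: Sequence[str]) -> LabeledDataset:
    """Measured-data import driven by a CSV manifest (file,label,group)."""
    import csv
    from pathlib import Path

    base = Path(manifest_csv).parent
    files, labels, groups = [], [], []
    with open(manifest_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            files.append(base / row["file"])
            labels.append(int(row["label"]))
            groups.append(int(row["group"]))
    return dataset_from_touchstone(files, labels, class_names, groups)
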