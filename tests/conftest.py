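"""Shared fixtures: phantoms at several sizes, written DICOM studies,
normalized volumes.  Everything is generated programmatically per session;
no data files are stored."""

from __future__ import annotations

import numpy as np
import pytest

from ctbodycomp import phantom as ph
from ctbodycomp.normalize import NormalizedVolume, normalize_acquisition


def small_spec(seed: int = 0, noise_sd: float = 0.0,
               plaques=(), organs=None, vertebra_levels=("L3", "L4", "L5"),
               hiatus=2, bifurcation=20) -> ph.PhantomSpec:
    """Compact phantom (64x64x24 @ 2.5x2.5x3 mm) for fast unit tests."""
    vertebrae = tuple(
        ph.VertebraDef(level=lev, center_slice=4 + 6 * k, body_radius_mm=12.0)
        for k, lev in enumerate(vertebra_levels)
    )
    if organs is None:
        organs = (
            ph.OrganDef("liver", "ellipsoid", (-25.0, -12.0, 45.0),
                        (18.0, 14.0, 12.0), 55.0),
        )
    return ph.PhantomSpec(
        grid_shape=(64, 64, 24),
        voxel_spacing_mm=(2.5, 2.5, 3.0),
        body_ellipse_mm=(72.0, 60.0),
        fat_ring_thickness_mm=10.0,
        muscle_ring_thickness_mm=8.0,
        organ_defs=tuple(organs),
        vertebra_defs=vertebrae,
        aorta=ph.AortaDef(center_xy_mm=(-5.0, 4.0), radius_mm=7.0,
                          slice_range=(2, 20)),
        plaque_defs=tuple(plaques),
        hiatus_slice=hiatus,
        bifurcation_slice=bifurcation,
        noise_sd=noise_sd,
        seed=seed,
    )


def random_plaques(spec: ph.PhantomSpec, rng: np.random.Generator,
                   n: int) -> tuple:
    """Random plaques fully contained in the spec's aorta cylinder."""
    ad = spec.aorta
    lo, hi = ad.slice_range
    dz = spec.voxel_spacing_mm[2]
    out = []
    for _ in range(n):
        r = float(rng.uniform(2.0, 5.0))
        theta = float(rng.uniform(0, 2 * np.pi))
        rho = float(rng.uniform(0, max(ad.radius_mm - r, 0.0)))
        zmin = spec.slice_z_mm(hi) + r
        zmax = spec.slice_z_mm(lo) - r
        z = float(rng.uniform(zmin, zmax))
        peak = float(rng.uniform(100.0, 900.0))
        out.append(ph.PlaqueDef(
            (ad.center_xy_mm[0] + rho * np.cos(theta),
             ad.center_xy_mm[1] + rho * np.sin(theta), z), r, peak))
    return tuple(out)


def volume_from_array(hu: np.ndarray, spacing=(1.0, 1.0, 3.0)) -> NormalizedVolume:
    """Wrap a raw-HU array as a NormalizedVolume (canonical orientation)."""
    offset = float(-hu.min())
    nz = hu.shape[0]
    return NormalizedVolume(
        voxels=hu + offset,
        spacing_mm=tuple(float(s) for s in spacing),
        intensity_offset=offset,
        orientation_canonical=True,
        provenance={"z_positions_mm": [(nz - 1 - i) * spacing[2]
                                       for i in range(nz)],
                    "transforms": [], "warnings": []},
    )


@pytest.fixture(scope="session")
def default_phantom():
    spec = ph.default_spec(seed=1)
    hu, truth = ph.build_phantom(spec)
    return spec, hu, truth


@pytest.fixture(scope="session")
def phantom_study_dir(tmp_path_factory, default_phantom):
    spec, hu, truth = default_phantom
    d = tmp_path_factory.mktemp("phantom_study")
    plan = ph.AcquisitionPlan(series=[ph.SeriesPlan(
        description="NON CONTRAST AXIAL")])
    ph.write_dicom_series(hu, spec, plan, str(d))
    ph.write_truth_sidecar(truth, str(d))
    return d


@pytest.fixture(scope="session")
def phantom_volume(phantom_study_dir):
    from ctbodycomp.ingest import scan_study, select_acquisition
    cat = scan_study(str(phantom_study_dir))
    files = select_acquisition(cat.series[0])
    return normalize_acquisition(files)


@pytest.fixture(scope="session")
def phantom_landmarks(phantom_volume, default_phantom):
    from ctbodycomp.landmarks import TruthLandmarkProvider, locate_landmarks
    _spec, _hu, truth = default_phantom
    return locate_landmarks(phantom_volume, TruthLandmarkProvider(truth))


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = ph.default_spec(seed=3, noise_sd=0.0)
    hu, truth = ph.build_phantom(spec)
    return spec, hu, truth


@pytest.fixture(scope="session")
def noise_free_volume(noise_free_phantom):
    return volume_from_array(noise_free_phantom[1], spacing=(2.5, 2.5, 3.0))
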