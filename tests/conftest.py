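"""Shared fixtures: synthetic systems generated fresh per test session."""

import numpy as np
import pytest

from carriermd import (
    BundleSpec,
    PocketSpec,
    TraceSpec,
    generate_bundle_trajectory,
    generate_ligand_pocket,
    generate_oxygraph_trace,
)


@pytest.fixture(scope="session")
def bundle():
    """Default six-helix bundle: radius 20 Å, 4 countable water crossings
    (3 up, 1 down), 3 far crossings and 2 periodic-boundary wrappers."""
    return generate_bundle_trajectory(BundleSpec(seed=7))


@pytest.fixture(scope="session")
def pocket_scheduled():
    """Pocket with scripted H-bond / pi / contact schedules."""
    n = 60
    spec = PocketSpec(
        residues={92: "ARG", 191: "GLU", 281: "TRP", 88: "PHE", 85: "GLN"},
        schedule={
            92: ["hbond"] * 30 + ["none"] * 30,
            191: ["hbond"] * 15 + ["none"] * 45,
            281: ["pi"] * 24 + ["none"] * 36,
            85: ["contact"] * 12 + ["none"] * 48,
            88: ["none"] * 60,
        },
        n_frames=n, seed=11)
    return generate_ligand_pocket(spec)


@pytest.fixture(scope="session")
def pocket_blobs():
    """Pocket with three planted pose blobs, occupancies 0.5/0.3/0.2.

    Blob separation is 10x the within-blob scatter (30 Å vs SD 3 Å)."""
    spec = PocketSpec(
        residues={10: "ALA", 20: "ALA", 30: "ALA", 40: "ALA"},
        schedule={}, n_frames=100, seed=5,
        pose_blobs=[(0.5, (0.0, 0.0, 0.0)),
                    (0.3, (30.0, 0.0, 0.0)),
                    (0.2, (0.0, 30.0, 0.0))],
        blob_sd=3.0)
    return generate_ligand_pocket(spec)


@pytest.fixture(scope="session")
def clean_trace():
    """Noise-free activity-assay trace with planted fluxes 5/10/30/15/50."""
    return generate_oxygraph_trace(TraceSpec(noise_sd=0.0, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
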