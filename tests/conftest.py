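"""Shared fixtures: synthetic restorations, supports and bone segments.

Expensive constructions (molar Boolean union, PDL merge) are built once
per session and reused; every test sees the same deterministic seed-0
geometry unless it builds its own.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from fpdgen import fixtures as fx
from fpdgen import pipeline as pl
from fpdgen.alignment import align_to_global
from fpdgen.implant import ImplantParams
from fpdgen.tooth import (
    ToothParams,
    make_cement_layer,
    make_pdl,
    make_pdl_for,
    make_single_root,
    make_two_root,
)

VOXEL_BUDGET = 2.5e6  # voxel budget for Boolean-heavy fixtures


@pytest.fixture(scope="session")
def tooth_fixture():
    return fx.make_fpd_fixture(fx.FixtureSpec(support_type="tooth", seed=0))


@pytest.fixture(scope="session")
def implant_fixture():
    return fx.make_fpd_fixture(fx.FixtureSpec(support_type="implant", seed=0))


@pytest.fixture(scope="session")
def aligned_tooth(tooth_fixture):
    model, _ = tooth_fixture
    return align_to_global(model)


@pytest.fixture(scope="session")
def aligned_implant(implant_fixture):
    model, _ = implant_fixture
    return align_to_global(model)


@pytest.fixture(scope="session")
def cement_premolar(aligned_tooth):
    return make_cement_layer(aligned_tooth.mesial, 0.1)


@pytest.fixture(scope="session")
def cement_molar(aligned_tooth):
    return make_cement_layer(aligned_tooth.distal, 0.1)


@pytest.fixture(scope="session")
def premolar(cement_premolar):
    return make_single_root(cement_premolar, ToothParams.premolar())


@pytest.fixture(scope="session")
def premolar_pdl(premolar):
    return make_pdl(premolar.root_surface, 0.3)


@pytest.fixture(scope="session")
def molar(cement_molar):
    return make_two_root(cement_molar, ToothParams.molar(), budget=VOXEL_BUDGET)


@pytest.fixture(scope="session")
def molar_pdl(molar):
    return make_pdl_for(molar, 0.3, budget=VOXEL_BUDGET)


@pytest.fixture(scope="session")
def tooth_build(aligned_tooth, cement_premolar, cement_molar, premolar,
                premolar_pdl, molar, molar_pdl):
    """SupportBuild assembled from the session parts (avoids rebuilding
    the molar union)."""
    from fpdgen.alignment import analyse

    lm = analyse(aligned_tooth)
    parts = {
        "cement_mesial": cement_premolar.mesh,
        "cement_distal": cement_molar.mesh,
        "tooth_mesial": premolar.solid,
        "tooth_distal": molar.solid,
        "pdl_mesial": premolar_pdl,
        "pdl_distal": molar_pdl,
    }
    return pl.SupportBuild(
        support_type="tooth",
        parts=parts,
        cavity_part_names=["pdl_mesial", "pdl_distal"],
        landmarks=lm,
        datums={
            "mesial": float(cement_premolar.c_interior.points[:, 2].min()),
            "distal": float(cement_molar.c_interior.points[:, 2].min()),
        },
    )


@pytest.fixture(scope="session")
def implant_build(aligned_implant):
    return pl.build_support(aligned_implant, "implant", budget=VOXEL_BUDGET)


@pytest.fixture(scope="session")
def bone_d1():
    return fx.make_bone_fixture("D1")


@pytest.fixture(scope="session")
def implant_insertion(implant_build, aligned_implant, bone_d1):
    return pl.insert_into_bone(
        implant_build, aligned_implant, bone_d1, budget=4.0e6
    )


@pytest.fixture(scope="session")
def tooth_insertion(tooth_build, aligned_tooth, bone_d1):
    return pl.insert_into_bone(
        tooth_build, aligned_tooth, bone_d1, budget=4.0e6
    )
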