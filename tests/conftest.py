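"""Shared fixtures: toy complexes and a session-wide template universe."""

from __future__ import annotations

import pytest

from tcrpmhc.core import Role
from tcrpmhc.fixtures import FixtureSpec, make_template_universe, make_toy_complex

ROLE_MAP = {"A": Role.MHC, "P": Role.PEPTIDE, "D": Role.TCRA, "E": Role.TCRB}


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(seed=1)


@pytest.fixture()
def role_map():
    return dict(ROLE_MAP)


@pytest.fixture(scope="session")
def universe():
    """Default 20-entry template universe (pMHC, TCR, TCR-pMHC dbs + manifest)."""
    spec = FixtureSpec(seed=7)
    pmhc_db, tcr_db, tcrpmhc_db, manifest = make_template_universe(spec)
    return {
        "spec": spec,
        "pmhc": pmhc_db,
        "tcr": tcr_db,
        "tcrpmhc": tcrpmhc_db,
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def isolated_universe():
    """Universe with one near-identical entry per target class and the rest
    remote, so the redundancy-aware selector keeps exactly one template for
    a target that matches a database entry."""
    spec = FixtureSpec(
        seed=13,
        n_entries=6,
        peptide_lengths={9: 6},
        identity_targets=(0.99, 0.75, 0.70, 0.65, 0.60, 0.55),
    )
    pmhc_db, tcr_db, tcrpmhc_db, manifest = make_template_universe(spec)
    return {
        "spec": spec,
        "pmhc": pmhc_db,
        "tcr": tcr_db,
        "tcrpmhc": tcrpmhc_db,
        "manifest": manifest,
    }
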