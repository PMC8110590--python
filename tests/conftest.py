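"""Shared fixtures: small synthetic surfaces and PDB fixture builders."""

from __future__ import annotations

import numpy as np
import pytest

from ocpkin.simulate import ocpww_preset, parallel3_preset, simulate_ta


def make_pdb_line(
    serial,
    name,
    resname,
    chain,
    resnum,
    x,
    y,
    z,
    occ=1.0,
    element=None,
    altloc=" ",
    het=False,
):
    """One fixed-column PDB coordinate record."""
    rec = "HETATM" if het else "ATOM  "
    element = element or name[0]
    nm = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{rec}{serial:>5} {nm}{altloc}{resname:>3} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{20.0:6.2f}          {element:>2}"
    )


@pytest.fixture(scope="session")
def ocpww_surface():
    """One noisy (SNR 100) surface of the five-state OCP condition."""
    cfg = ocpww_preset(seed=11)
    return cfg, simulate_ta(cfg)


@pytest.fixture(scope="session")
def parallel3_surface():
    """One noisy (SNR 100) three-component parallel surface."""
    cfg = parallel3_preset(seed=7)
    return cfg, simulate_ta(cfg)


@pytest.fixture()
def toy_dataset():
    from ocpkin.dataset import TADataset

    return TADataset(
        wavelengths=np.array([450.0, 500.0, 650.0, 700.0]),
        delays=np.array([-0.1, 0.0, 1.0]),
        delta_A=np.arange(12, dtype=float).reshape(3, 4),
    )
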