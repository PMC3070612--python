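import numpy as np
import pytest

from toxscape.containers import Region, ReleaseSite


def make_lattice_regions(side, cell=1.0, codes=None, covariates=None, outcomes=None):
    """side x side unit-cell regions, ids row-major, centroids at cell centers."""
    regions = []
    for iy in range(side):
        for ix in range(side):
            j = iy * side + ix
            regions.append(
                Region(
                    id=j,
                    x=(ix + 0.5) * cell,
                    y=(iy + 0.5) * cell,
                    rural_urban_code=codes[j] if codes is not None else 5,
                    outcome=outcomes[j] if outcomes is not None else float("nan"),
                    covariates=covariates[j] if covariates is not None else {},
                )
            )
    return regions


@pytest.fixture
def grid3():
    return make_lattice_regions(3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_site(i, x, y, region_id, volume=10000.0, chem="all_carcinogen"):
    return ReleaseSite(id=f"s{i}", x=x, y=y, region_id=region_id, volume=volume, chemical_class=chem)
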