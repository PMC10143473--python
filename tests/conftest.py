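import io

import numpy as np
import pytest

from soilcr import (
    BackgroundTable,
    RegionRecord,
    default_paperlike_spec,
    generate_regions,
)


@pytest.fixture
def national_bg():
    return BackgroundTable()


@pytest.fixture
def small_records():
    """Three hand-written regions covering distinct types and provinces."""
    return [
        RegionRecord("r1", "Zhejiang", "C", 2500.0, sampling_year=2010),
        RegionRecord("r2", "Hunan", "M", 61.0, sampling_year=2015),
        RegionRecord("r3", "Shandong", "T", 91.5, sampling_year=2020),
    ]


@pytest.fixture
def small_csv():
    return io.StringIO(
        "region_id,province,city,industry_type,sampling_year,depth_cm,cr_conc,source\n"
        "r1,Zhejiang,Hangzhou,C,2010,20,2500.0,ref-a\n"
        "r2,Hunan,,M,2015,,61.0,\n"
        "r3,Shandong,Jinan,T,2020,50,91.5,ref-b\n"
    )


@pytest.fixture(scope="session")
def paperlike_table():
    """One seeded draw from the default generator at the study size."""
    return generate_regions(default_paperlike_spec(seed=20240101, n_regions=506))


def make_conc_records(concs, province="Hunan", industry_type="M", year=None):
    """Region records with prescribed concentrations, for arithmetic fixtures."""
    return [
        RegionRecord(f"x{i}", province, industry_type, float(c), sampling_year=year)
        for i, c in enumerate(concs)
    ]
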