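import pandas as pd
import pytest

from artcea.cohort import CohortParams, Cohort, generate_cohort
from artcea.costing import UnitCostTable


@pytest.fixture(scope="session")
def unit_costs() -> UnitCostTable:
    return UnitCostTable.default()


@pytest.fixture(scope="session")
def small_params() -> CohortParams:
    return CohortParams(n_per_arm=(150, 150), seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_params) -> Cohort:
    return generate_cohort(small_params)


@pytest.fixture(scope="session")
def full_cohort() -> Cohort:
    """Trial-sized cohort under the default study conditions."""
    return generate_cohort(CohortParams(), seed=1)


@pytest.fixture()
def mirrored_cohort(small_cohort) -> Cohort:
    """Cohort whose CDM arm is the LCM arm relabelled: identical
    histories, so every between-arm difference must vanish."""
    pats = small_cohort.patients[small_cohort.patients["arm"] == "LCM"].copy()
    cyc = small_cohort.cycles[small_cohort.cycles["id"].isin(pats["id"])].copy()
    pats2 = pats.copy()
    offset = int(small_cohort.patients["id"].max()) + 1
    pats2["id"] = pats2["id"] + offset
    pats2["arm"] = "CDM"
    cyc2 = cyc.copy()
    cyc2["id"] = cyc2["id"] + offset
    return Cohort(
        patients=pd.concat([pats, pats2], ignore_index=True),
        cycles=pd.concat([cyc, cyc2], ignore_index=True),
        params=small_cohort.params,
    )


@pytest.fixture(scope="session")
def equal_concomitant_costs(unit_costs) -> UnitCostTable:
    """Unit costs with identical per-arm concomitant amounts, so mirrored
    arms cost out identically."""
    frame = unit_costs.frame.copy()
    frame.loc[frame["item"] == "concomitant_flat_cdm", "price_usd_2008"] = float(
        frame.loc[frame["item"] == "concomitant_flat_lcm", "price_usd_2008"].iloc[0]
    )
    return UnitCostTable(frame)
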