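"""Sample design tables for barcoded-library colonization experiments.

A design table describes one sequencing sample per row: which habitat it
came from (bulk soil, or the root/shoot of one of the two hosts), whether
the focal strain was inoculated together with a small auxiliary bacterial
community, on which of the two harvest days it was processed, and which
growth flat it belongs to.  Soil samples double as the reference (T0-like)
population for fitness scoring and as the comparison group of the
differential-fitness regression.
"""

from __future__ import annotations

import itertools

import pandas as pd

#: The five habitats of the colonization experiment.
HABITATS = ("soil", "At_root", "At_shoot", "Bd_root", "Bd_shoot")

#: The four plant habitats (contrasts are each of these versus soil).
PLANT_HABITATS = ("At_root", "At_shoot", "Bd_root", "Bd_shoot")

DESIGN_COLUMNS = ("sample_id", "habitat", "auxiliary_community", "harvest_day", "flat")


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a design table.

    Requires the columns in :data:`DESIGN_COLUMNS`, habitats drawn from the
    fixed five-level set, at least two soil samples, and unique sample ids.
    Returns a copy with canonical dtypes.
    """
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    out = design.loc[:, list(DESIGN_COLUMNS)].copy()
    bad = set(out["habitat"]) - set(HABITATS)
    if bad:
        raise ValueError(f"unknown habitats in design: {sorted(bad)}")
    if out["sample_id"].duplicated().any():
        raise ValueError("sample ids must be unique")
    if (out["habitat"] == "soil").sum() < 2:
        raise ValueError("design requires at least two soil samples")
    if not out["harvest_day"].isin([1, 2]).all():
        raise ValueError("harvest_day must be 1 or 2")
    out["auxiliary_community"] = out["auxiliary_community"].astype(bool)
    out["harvest_day"] = out["harvest_day"].astype(int)
    out["flat"] = out["flat"].astype(int)
    return out


def soil_samples(design: pd.DataFrame) -> list[str]:
    """Sample ids of the soil (reference) samples."""
    return list(design.loc[design["habitat"] == "soil", "sample_id"])


def make_design(
    n_per_habitat: int = 6,
    n_soil: int = 6,
    n_flats: int = 6,
) -> pd.DataFrame:
    """Build a balanced design table.

    ``n_per_habitat`` samples for each of the four plant habitats plus
    ``n_soil`` soil samples.  Auxiliary-community status and harvest day
    alternate within each habitat so that both covariates vary in every
    habitat-vs-soil contrast; flats are assigned round-robin.
    """
    if n_per_habitat < 1 or n_soil < 2 or n_flats < 1:
        raise ValueError("need n_per_habitat >= 1, n_soil >= 2, n_flats >= 1")
    rows = []
    flat_cycle = itertools.cycle(range(1, n_flats + 1))
    for habitat in ("soil",) + PLANT_HABITATS:
        n = n_soil if habitat == "soil" else n_per_habitat
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{habitat}_{i + 1:02d}",
                    "habitat": habitat,
                    "auxiliary_community": bool(i % 2),
                    "harvest_day": 1 + (i // 2) % 2,
                    "flat": next(flat_cycle),
                }
            )
    return validate_design(pd.DataFrame(rows))
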