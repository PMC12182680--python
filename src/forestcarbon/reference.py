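"""Bundled reference parameter set: published growth-model fits.

A national compilation of field surveys yields one selected
climate-augmented growth model per primary forest type; the fitted
parameters are bundled here so worked examples and downstream projections
can be driven by a published parameter set instead of a synthetic fit.
"""

from __future__ import annotations

import json
from importlib import resources

from .growth import GrowthFit

_DATA = "published_growth_fits.json"


def published_fits() -> dict[str, GrowthFit]:
    """Load the bundled published fits, keyed by forest-type label."""
    payload = json.loads(
        resources.files("forestcarbon.data").joinpath(_DATA).read_text())
    out: dict[str, GrowthFit] = {}
    for row in payload["fits"]:
        out[row["label"]] = GrowthFit(
            family=row["family"], mu=row["mu"], k=row.get("k"),
            c=row.get("c"), alpha=row.get("alpha"), a=row["a"], b=row["b"],
            d=row["d"], rmse=row["rmse"], r2=row["r2"], aic=row["aic"],
            n=row["n"], label=row["label"])
    return out
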