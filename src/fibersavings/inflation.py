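"""Cost inflation via an annual medical-care price index series.

Costs published for different years are brought to a common reporting year
by the ratio of annual-average index values, the standard medical-care CPI
adjustment. The series is plain user data (a two-column year/index CSV); a
small packaged series of U.S. medical-care CPI annual averages covers
2000-2012 for tests and examples.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from pydantic import ConfigDict, RootModel, model_validator

__all__ = ["PriceIndexSeries", "inflate", "read_index_csv", "packaged_medical_cpi"]


class PriceIndexSeries(RootModel[dict[int, float]]):
    """Mapping calendar year -> annual-average price index (> 0)."""

    model_config = ConfigDict(validate_assignment=True)

    @model_validator(mode="after")
    def _positive(self) -> "PriceIndexSeries":
        for year, value in self.root.items():
            if value <= 0:
                raise ValueError(f"index value for {year} must be > 0, got {value}")
        return self

    def __getitem__(self, year: int) -> float:
        try:
            return self.root[year]
        except KeyError:
            raise KeyError(f"year {year} not in price index series") from None

    def __contains__(self, year: int) -> bool:
        return year in self.root

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.root))


def inflate(
    cost: float, from_year: int, to_year: int, idx: PriceIndexSeries
) -> float:
    """Re-express ``cost`` (USD of ``from_year``) in ``to_year`` dollars."""
    return cost * idx[to_year] / idx[from_year]


def read_index_csv(path: str | Path) -> PriceIndexSeries:
    """Read a two-column ``year,index`` CSV into a series."""
    df = pd.read_csv(path)
    missing = {"year", "index"} - set(df.columns)
    if missing:
        raise ValueError(f"index CSV missing column(s): {sorted(missing)}")
    return PriceIndexSeries(dict(zip(df["year"].astype(int), df["index"].astype(float))))


def packaged_medical_cpi() -> PriceIndexSeries:
    """The packaged U.S. medical-care CPI annual-average series."""
    from importlib import resources

    path = resources.files("fibersavings").joinpath("data/medical_care_cpi.csv")
    return read_index_csv(Path(str(path)))
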