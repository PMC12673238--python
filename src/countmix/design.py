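"""Survey design: dimensions and treatment layout of a repeated-count study.

A *unit* is one site x species x year combination; all likelihoods in this
package are indexed by units. Within a unit there are ``n_surveys`` repeated
sampling events (J, typically 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def default_restored(n_sites: int) -> tuple[int, ...]:
    """Alternating 0/1 treatment assignment; exactly half restored when even."""
    return tuple(int(i % 2 == 0) for i in range(n_sites))


@dataclass(frozen=True)
class SurveyDesign:
    """Dimensions and site-level treatment assignment of a study.

    Parameters
    ----------
    n_sites, n_species, n_years, n_surveys
        Study dimensions. ``n_surveys`` is the number of repeated sampling
        events J within each site x species x year unit.
    restored
        Binary flag per site (1 = restored, 0 = control). When omitted,
        sites alternate between treatments so that exactly half are
        restored for even ``n_sites``.
    """

    n_sites: int
    n_species: int
    n_years: int = 2
    n_surveys: int = 3
    restored: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("n_sites", "n_species", "n_years", "n_surveys"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.restored is None:
            object.__setattr__(self, "restored", default_restored(self.n_sites))
        else:
            object.__setattr__(self, "restored", tuple(int(r) for r in self.restored))
        if len(self.restored) != self.n_sites:
            raise ValueError(
                f"restored has length {len(self.restored)}, expected {self.n_sites}"
            )
        if any(r not in (0, 1) for r in self.restored):
            raise ValueError("restored flags must be 0 or 1")

    @property
    def n_units(self) -> int:
        return self.n_sites * self.n_species * self.n_years

    def units(self) -> pd.DataFrame:
        """Table of all site x species x year units, with the restored flag.

        Rows are ordered by (site, species, year); the row position is the
        unit index ``i`` used throughout the package.
        """
        site, species, year = np.meshgrid(
            np.arange(self.n_sites),
            np.arange(self.n_species),
            np.arange(self.n_years),
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "site": site.ravel(),
                "species": species.ravel(),
                "year": year.ravel(),
            }
        )
        df["restored"] = np.asarray(self.restored)[df["site"].to_numpy()]
        return df
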