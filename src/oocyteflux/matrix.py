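"""Metabolite x sample abundance container shared by QC and profiling.

Values are quantifier-ion (EIC) peak heights in arbitrary MS abundance units.
Heights below the detection floor are reported at the floor and flagged in the
``censored`` mask rather than treated as zeros. Sample metadata (role,
transporter, timepoint/phase, replicate, injection order, ribitol height)
travels with the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["AbundanceMatrix"]


@dataclass
class AbundanceMatrix:
    #: rows = metabolites, columns = sample ids
    values: pd.DataFrame
    #: one row per sample id: role, transporter, timepoint, phase, replicate,
    #: injection_order, ribitol_height
    samples: pd.DataFrame
    #: boolean mask, same shape as ``values``: height reported at the floor
    censored: pd.DataFrame | None = None
    #: ribitol heights kept aside as the negative-control channel once the
    #: internal-standard row is stripped from the analysis matrix
    negative_control: pd.Series | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns)
        if not self.values.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.values.columns]
        if (self.values.values < 0).any():
            raise ValueError("abundance values must be non-negative")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            values=self.values.copy(),
            samples=self.samples.copy(),
            censored=self.censored.copy(),
            negative_control=None if self.negative_control is None
            else self.negative_control.copy(),
            log=list(self.log),
        )

    def drop_samples(self, sample_ids) -> "AbundanceMatrix":
        keep = [c for c in self.values.columns if c not in set(sample_ids)]
        return AbundanceMatrix(
            values=self.values[keep],
            samples=self.samples.loc[keep],
            censored=self.censored[keep],
            negative_control=None if self.negative_control is None
            else self.negative_control.loc[keep],
            log=list(self.log),
        )

    def drop_metabolites(self, names) -> "AbundanceMatrix":
        keep = [m for m in self.values.index if m not in set(names)]
        return AbundanceMatrix(
            values=self.values.loc[keep],
            samples=self.samples.copy(),
            censored=self.censored.loc[keep],
            negative_control=None if self.negative_control is None
            else self.negative_control.copy(),
            log=list(self.log),
        )

    def biological(self) -> "AbundanceMatrix":
        """Subset to oocyte-derived samples (transporter + uninjected)."""
        keep = self.samples.index[self.samples["role"].isin(
            ["transporter", "uninjected"])]
        drop = [c for c in self.values.columns if c not in set(keep)]
        return self.drop_samples(drop)
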