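"""Packaged reference data: metabolite library and transporter fixtures.

The metabolite library plays the role of an in-house MSRI library for a
single-quadrupole GC-MS workflow: each entry carries a Kovats retention index,
an electron-impact fragment spectrum (max-normalized), the quantifier (EIC)
ion used for quantification, a response-factor class, the proportions of its
trimethylsilyl (TMS) derivative variants, and any on-column conversion
products (arginine -> ornithine, glutamate/glutamine -> pyroglutamate).

Quantifier ions for the 20 proteinogenic amino acids are the published EIC
values; fragment intensities and most retention indices are fixed synthetic
stand-ins (see the fixture header).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "MetaboliteRecord",
    "TransporterModel",
    "load_reference_library",
    "load_transporter_models",
    "get_metabolite",
    "get_transporter",
    "AMINO_ACIDS",
    "ENDOGENOUS_UM",
    "ENDOGENOUS_PMOL",
    "ENDOGENOUS_SUPPLEMENT_PMOL",
    "LOW_RF_AMINO_ACIDS",
    "ALKANE_CARBONS",
    "SCAN_MZ_MIN",
    "SCAN_MZ_MAX",
    "OOCYTE_VOLUME_NL",
]

SCAN_MZ_MIN = 40
SCAN_MZ_MAX = 600
ALKANE_CARBONS = (12, 15, 19, 22, 28, 33, 36)

#: Water-accessible volume of a stage 5-6 oocyte (nL).
OOCYTE_VOLUME_NL = 365.0

#: The 20 proteinogenic amino acids, in the order of the endogenous-pool table.
AMINO_ACIDS = (
    "Valine", "Leucine", "Isoleucine", "Proline", "Glycine", "Serine",
    "Alanine", "Threonine", "Aspartic acid", "Methionine", "Cysteine",
    "Glutamic acid", "Phenylalanine", "Asparagine", "Glutamine", "Arginine",
    "Lysine", "Histidine", "Tyrosine", "Tryptophan",
)

#: Amino acids with poor GC-MS response factors (loaded at 10x in standards).
LOW_RF_AMINO_ACIDS = frozenset(
    {"Arginine", "Alanine", "Histidine", "Tryptophan", "Cysteine"})

#: Published free endogenous amino-acid concentrations in stage 5-6 oocytes (uM).
ENDOGENOUS_UM = {
    "Valine": 499, "Leucine": 77, "Isoleucine": 110, "Proline": 310,
    "Glycine": 64, "Serine": 290, "Alanine": 222, "Threonine": 96,
    "Aspartic acid": 2349, "Methionine": 124, "Cysteine": 58,
    "Glutamic acid": 1869, "Phenylalanine": 93, "Asparagine": 650,
    "Glutamine": 1455, "Arginine": 288, "Lysine": 85, "Histidine": 121,
    "Tyrosine": 493, "Tryptophan": 33,
}

#: Published endogenous pools (pmol/oocyte), i.e. uM x 0.365 after rounding.
ENDOGENOUS_PMOL = {
    "Valine": 182, "Leucine": 28, "Isoleucine": 40, "Proline": 113,
    "Glycine": 23, "Serine": 106, "Alanine": 81, "Threonine": 35,
    "Aspartic acid": 857, "Methionine": 45, "Cysteine": 21,
    "Glutamic acid": 682, "Phenylalanine": 34, "Asparagine": 237,
    "Glutamine": 531, "Arginine": 105, "Lysine": 31, "Histidine": 44,
    "Tyrosine": 180, "Tryptophan": 12,
}

#: Fixture pools (pmol/oocyte) for non-amino-acid metabolites the simulator
#: carries alongside the published amino-acid pools.
ENDOGENOUS_SUPPLEMENT_PMOL = {
    "Ornithine": 30.0,
    "Pyroglutamic acid": 0.0,  # produced on-column from Glu/Gln
    "Citric acid": 400.0,
    "Pantothenic acid": 50.0,
    "Sucrose": 2000.0,
}

_RF_CLASSES = ("high", "medium", "low")
_MECHANISMS = ("symport", "antiport", "uniport", "none")


@dataclass(frozen=True)
class MetaboliteRecord:
    """One reference-library entry."""

    name: str
    metabolite_class: str
    retention_index: float
    spectrum: tuple[tuple[int, float], ...]
    quantifier_mz: int
    rf_class: str
    mw: float
    #: (label, proportion, retention_index) per TMS derivative variant.
    tms_variants: tuple[tuple[str, float, float], ...]
    #: (product_name, fraction) of signal converted on-column to another entry.
    conversion_products: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def validate(self) -> None:
        if not self.spectrum:
            raise ValueError(f"{self.name}: empty spectrum")
        mzs = [mz for mz, _ in self.spectrum]
        if len(set(mzs)) != len(mzs):
            raise ValueError(f"{self.name}: duplicate m/z in spectrum")
        for mz, rel in self.spectrum:
            if not (SCAN_MZ_MIN <= mz <= SCAN_MZ_MAX):
                raise ValueError(f"{self.name}: m/z {mz} outside scan range")
            if not (0.0 < rel <= 1.0):
                raise ValueError(f"{self.name}: intensity {rel} outside (0, 1]")
        if abs(max(rel for _, rel in self.spectrum) - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: spectrum not max-normalized")
        if self.quantifier_mz not in set(mzs):
            raise ValueError(f"{self.name}: quantifier {self.quantifier_mz} "
                             "absent from spectrum")
        if self.rf_class not in _RF_CLASSES:
            raise ValueError(f"{self.name}: unknown rf_class {self.rf_class!r}")
        total = sum(p for _, p, _ in self.tms_variants)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: TMS proportions sum to {total}")
        if self.metabolite_class == "amino_acid" and \
                self.name not in ("Aspartic acid", "Serine"):
            if max(p for _, p, _ in self.tms_variants) < 0.8:
                raise ValueError(f"{self.name}: no dominant TMS variant")

    @property
    def dominant_variant(self) -> tuple[str, float, float]:
        return max(self.tms_variants, key=lambda v: v[1])

    def intensity_at(self, mz: int) -> float:
        for m, rel in self.spectrum:
            if m == mz:
                return rel
        return 0.0


@dataclass(frozen=True)
class TransporterModel:
    """A heterologously expressed transporter, reduced to its mechanism and a
    Michaelis-Menten parameter pair per substrate.

    Ion-coupling stoichiometry is carried as descriptive metadata only; the
    electrochemical driving force is collapsed into Vmax.
    """

    name: str
    mechanism: str
    #: substrate name -> (Km uM, Vmax pmol/oocyte/h)
    substrates: dict[str, tuple[float, float]]
    stoichiometry: str = ""

    def validate(self) -> None:
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"{self.name}: unknown mechanism {self.mechanism!r}")
        if self.mechanism == "none" and self.substrates:
            raise ValueError(f"{self.name}: mechanism 'none' with substrates")
        for sub, (km, vmax) in self.substrates.items():
            if km <= 0:
                raise ValueError(f"{self.name}/{sub}: Km must be > 0")
            if vmax < 0:
                raise ValueError(f"{self.name}/{sub}: Vmax must be >= 0")


def _read_fixture(fname: str) -> dict:
    path = resources.files("oocyteflux") / "data" / fname
    with path.open("r") as fh:
        return json.load(fh)


def load_reference_library() -> list[MetaboliteRecord]:
    """Load and validate the packaged metabolite library.

    Raises ``ValueError`` naming the offending record if the fixture is
    corrupted.
    """
    raw = _read_fixture("metabolite_library.json")
    records = []
    for entry in raw["metabolites"]:
        rec = MetaboliteRecord(
            name=entry["name"],
            metabolite_class=entry["class"],
            retention_index=float(entry["retention_index"]),
            spectrum=tuple((int(mz), float(rel)) for mz, rel in entry["spectrum"]),
            quantifier_mz=int(entry["quantifier_mz"]),
            rf_class=entry["rf_class"],
            mw=float(entry["mw"]),
            tms_variants=tuple(
                (v["label"], float(v["proportion"]), float(v["retention_index"]))
                for v in entry["tms_variants"]),
            conversion_products=tuple(
                (c["product"], float(c["fraction"]))
                for c in entry.get("conversion_products", [])),
        )
        rec.validate()
        records.append(rec)
    names = {r.name for r in records}
    missing = set(AMINO_ACIDS) - names
    if missing:
        raise ValueError(f"library is missing amino acids: {sorted(missing)}")
    return records


def load_transporter_models() -> list[TransporterModel]:
    """Load and validate the packaged transporter fixtures."""
    raw = _read_fixture("transporters.json")
    models = []
    for entry in raw["transporters"]:
        model = TransporterModel(
            name=entry["name"],
            mechanism=entry["mechanism"],
            substrates={k: (float(km), float(vm))
                        for k, (km, vm) in entry["substrates"].items()},
            stoichiometry=entry.get("stoichiometry", ""),
        )
        model.validate()
        models.append(model)
    return models


def get_metabolite(name: str,
                   library: list[MetaboliteRecord] | None = None) -> MetaboliteRecord:
    for rec in library if library is not None else load_reference_library():
        if rec.name == name:
            return rec
    raise KeyError(f"metabolite {name!r} not in reference library")


def get_transporter(name: str) -> TransporterModel:
    models = load_transporter_models()
    for model in models:
        if model.name == name:
            return model
    available = ", ".join(m.name for m in models)
    raise KeyError(f"transporter {name!r} unknown; available: {available}")
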