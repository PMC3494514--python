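"""Quantifier-ion derivation and offline compound-ID annotation.

Targeted LC-MS quantification traces a single quantifier m/z per compound.
For electrospray ionisation the dominant adducts are [M+H]+ in positive mode
and [M-H]- in negative mode, so the quantifier is derived from the (mono-
isotopic) molecular weight by adding or subtracting one proton mass.  Compound
names are mapped to PubChem / KEGG / HMDB identifiers through a packaged
offline table, so the whole pipeline runs without network access.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .errors import DomainError, ValidationError

logger = logging.getLogger(__name__)

#: Proton mass in Da used for the [M+H]+ / [M-H]- adduct arithmetic.
PROTON_MASS = 1.00728

_ID_COLUMNS = ("pubchem", "kegg", "hmdb")


@dataclass
class Metabolite:
    """One compound on the quantification-ion list.

    Parameters
    ----------
    name:
        Compound name as given by the analyst.
    quant_mz:
        Quantifier m/z (Th) traced for this compound.  May be derived from
        ``molecular_weight`` via :func:`quant_ion_mz`.
    expected_rt:
        Expected retention time in minutes; seeded from the first standard
        run and required before calibration.
    is_internal_standard:
        At most one metabolite per project carries this flag; analyte areas
        are divided by its area before calibration and quantification.
    ids:
        Database identifiers, keys among ``pubchem``/``kegg``/``hmdb``.
    extra:
        Opaque per-row metadata preserved through CSV round-trips.
    """

    name: str
    quant_mz: Optional[float] = None
    molecular_weight: Optional[float] = None
    expected_rt: Optional[float] = None
    is_internal_standard: bool = False
    ionisation_mode: str = "positive"
    ids: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.quant_mz is not None and self.quant_mz <= 0:
            raise ValidationError(f"{self.name}: quant_mz must be positive")


def quant_ion_mz(molecular_weight: float, mode: str,
                 adduct_shift: float = PROTON_MASS) -> float:
    """Derive the quantifier m/z from molecular weight and ionisation mode.

    Positive mode returns ``MW + adduct_shift`` (protonation), negative mode
    ``MW - adduct_shift`` (deprotonation).  ``adduct_shift`` defaults to one
    proton mass but can be overridden for other single-charge adducts.
    """
    if molecular_weight <= 0:
        raise DomainError("molecular weight must be positive")
    if mode == "positive":
        return molecular_weight + adduct_shift
    if mode == "negative":
        mz = molecular_weight - adduct_shift
        if mz <= 0:
            raise DomainError(
                f"negative-mode quantifier non-positive for MW "
                f"{molecular_weight} Da (below the adduct shift)")
        return mz
    raise DomainError(f"unknown ionisation mode {mode!r}")


def quant_ion_mw(quant_mz: float, mode: str,
                 adduct_shift: float = PROTON_MASS) -> float:
    """Inverse of :func:`quant_ion_mz`: recover MW from a quantifier m/z."""
    if mode == "positive":
        return quant_mz - adduct_shift
    if mode == "negative":
        return quant_mz + adduct_shift
    raise DomainError(f"unknown ionisation mode {mode!r}")


def load_id_table(path=None) -> pd.DataFrame:
    """Load the offline compound-ID table (packaged CSV by default).

    Columns: ``name``, ``pubchem_cid``, ``kegg_id``, ``hmdb_id``,
    ``monoisotopic_mw``.  The packaged table is a curated offline snapshot of
    the cross-referenced public databases, covering the amino acids and
    central-carbon organic acids typical of targeted cell-culture panels.
    """
    if path is None:
        with resources.files("lcquant.data").joinpath(
                "compound_ids.csv").open("r", encoding="utf-8") as fh:
            return pd.read_csv(fh, dtype=str)
    return pd.read_csv(path, dtype=str)


def _normalize_name(name: str) -> str:
    return re.sub(r"[^0-9a-z]", "", name.lower())


def lookup_compound(name: str, table: Optional[pd.DataFrame] = None) -> dict:
    """Map a compound name to its database IDs from the offline table.

    Matching is case-insensitive exact first, then punctuation-insensitive
    (non-alphanumerics stripped).  A miss returns an empty map with a logged
    warning — identifiers are only required at export time, so the pipeline
    continues.  An ambiguous name matching several rows is an error: a silent
    arbitrary pick could key the exported table to the wrong compound.
    """
    if table is None:
        table = load_id_table()
    lowered = table["name"].str.lower()
    hits = table[lowered == name.lower()]
    if len(hits) == 0:
        normalized = table["name"].map(_normalize_name)
        hits = table[normalized == _normalize_name(name)]
    if len(hits) == 0:
        logger.warning("no ID-table entry for compound %r", name)
        return {}
    if len(hits) > 1:
        raise ValidationError(
            f"ambiguous compound name {name!r}: matches "
            f"{', '.join(hits['name'])}")
    row = hits.iloc[0]
    ids = {}
    for key, col in (("pubchem", "pubchem_cid"), ("kegg", "kegg_id"),
                     ("hmdb", "hmdb_id")):
        value = row.get(col)
        if isinstance(value, str) and value.strip():
            ids[key] = value.strip()
    if isinstance(row.get("monoisotopic_mw"), str) and row["monoisotopic_mw"]:
        ids["monoisotopic_mw"] = float(row["monoisotopic_mw"])
    return ids


def annotate(metabolite: Metabolite,
             table: Optional[pd.DataFrame] = None) -> Metabolite:
    """Fill a metabolite's ID map (and MW, if missing) from the offline table."""
    found = lookup_compound(metabolite.name, table)
    mw = found.pop("monoisotopic_mw", None)
    metabolite.ids.update({k: v for k, v in found.items()
                           if k not in metabolite.ids})
    if metabolite.molecular_weight is None and mw is not None:
        metabolite.molecular_weight = mw
    if metabolite.quant_mz is None and metabolite.molecular_weight is not None:
        metabolite.quant_mz = quant_ion_mz(metabolite.molecular_weight,
                                           metabolite.ionisation_mode)
    return metabolite
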