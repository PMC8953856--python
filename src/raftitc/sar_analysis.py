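"""Structure-affinity post-processing of fitted K_D tables.

Positional-scan ladders (Ala-scan: side-chain removal; D-scan:
stereochemical inversion; beta-scan: backbone homologation to
beta3-amino acids) are summarized as binding free-energy changes
relative to the parent sequence,

    ddG = R * T * ln(K_D,variant / K_D,parent)   [kcal/mol],

positive = destabilizing.  Cells where the titration could not be
fitted ("n.f.") are treated as right-censored -- at least as
destabilizing as the largest observed ddG -- and never imputed or
ranked as finite values.  A small avidity utility quantifies the
affinity gain of multivalent presentation on a hub protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Gas constant in kcal/(mol K).
R_KCAL_PER_MOL_K = 1.98720e-3
#: ITC measurement temperature (35 C).
ITC_TEMPERATURE_K = 308.15

SCAN_KINDS = ("ala", "d", "beta")


@dataclass
class ScanTable:
    """Parent + positional-variant K_D matrix.

    ``kd_nm`` is indexed by scan kind ('ala', 'd', 'beta') with one
    column per parent position (e.g. W1..W5); NaN cells mark
    not-fittable (censored) titrations.
    """

    parent_kd_nm: float
    kd_nm: pd.DataFrame
    sequence: str = "WYKYW"
    temperature_k: float = ITC_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.parent_kd_nm <= 0:
            raise ValueError("parent_kd_nm must be positive")
        if self.kd_nm.empty:
            raise ValueError("scan table is empty")
        unknown = set(self.kd_nm.index) - set(SCAN_KINDS)
        if unknown:
            raise ValueError(f"unknown scan kinds: {sorted(unknown)}")
        if len(self.kd_nm.columns) != len(self.sequence):
            raise ValueError("number of positions must match the parent sequence length")
        vals = self.kd_nm.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("all fitted K_D values must be positive")

    @property
    def censored(self) -> pd.DataFrame:
        """Boolean mask of not-fittable cells."""
        return self.kd_nm.isna()


@dataclass(frozen=True)
class AvidityPair:
    """Monovalent vs multivalent affinities of the same carrier.

    Defaults are the measured pair for the hub-displayed carrier:
    332 nM monomer (2:1 carrier:GM1 stoichiometry) vs 38 nM for the
    tetravalent hub construct (1:1 per hub).
    """

    kd_monomer_nm: float = 332.0
    kd_multivalent_nm: float = 38.0
    stoichiometry_monomer: str = "2:1"
    stoichiometry_multivalent: str = "1:1"

    def __post_init__(self) -> None:
        if self.kd_monomer_nm <= 0 or self.kd_multivalent_nm <= 0:
            raise ValueError("both K_D values must be positive")


@dataclass
class ScanProfile:
    """Per-position, per-scan ddG summary of a :class:`ScanTable`."""

    ddg_kcal: pd.DataFrame
    fold_change: pd.DataFrame
    censored: pd.DataFrame
    #: finite cells ordered most- to least-destabilizing
    ranking: list[tuple[str, str, float]]
    #: censored cells, each a lower bound >= censored_floor_kcal
    censored_cells: list[tuple[str, str]] = field(default_factory=list)
    censored_floor_kcal: float = math.nan
    #: cells with improved affinity over the parent (ddG < 0)
    improvements: list[tuple[str, str, float]] = field(default_factory=list)


def ddg(
    variant_kd_nm: float,
    parent_kd_nm: float,
    temperature_k: float = ITC_TEMPERATURE_K,
) -> float:
    """Binding free-energy change of a variant relative to the parent.

    Positive values are destabilizing; the function is antisymmetric
    under swapping variant and parent.  A NaN variant (not-fittable,
    censored) propagates as NaN.
    """
    if isinstance(variant_kd_nm, float) and math.isnan(variant_kd_nm):
        return math.nan
    if variant_kd_nm <= 0 or parent_kd_nm <= 0:
        raise ValueError("K_D values must be positive")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL_PER_MOL_K * temperature_k * math.log(variant_kd_nm / parent_kd_nm)


def scan_profile(table: ScanTable) -> ScanProfile:
    """ddG / fold-change matrices with a destabilization ranking.

    Censored (not-fittable) cells are excluded from the finite ranking
    and reported separately as lower bounds at least as large as the
    maximum observed ddG.  Cells with ddG < 0 (affinity improved over
    the parent, seen for terminal backbone homologation) are flagged.
    """
    kd = table.kd_nm.astype(float)
    rt = R_KCAL_PER_MOL_K * table.temperature_k
    ddg_df = rt * np.log(kd / table.parent_kd_nm)
    fold = kd / table.parent_kd_nm
    censored = table.censored

    finite = [
        (scan, pos, float(ddg_df.loc[scan, pos]))
        for scan in ddg_df.index
        for pos in ddg_df.columns
        if not censored.loc[scan, pos]
    ]
    ranking = sorted(finite, key=lambda item: item[2], reverse=True)
    censored_cells = [
        (scan, pos)
        for scan in censored.index
        for pos in censored.columns
        if censored.loc[scan, pos]
    ]
    floor = max((v for *_, v in finite), default=math.nan)
    improvements = [(s, p, v) for s, p, v in finite if v < 0]
    return ScanProfile(
        ddg_kcal=ddg_df, fold_change=fold, censored=censored,
        ranking=ranking, censored_cells=censored_cells,
        censored_floor_kcal=floor, improvements=improvements,
    )


def avidity_enhancement(pair: AvidityPair) -> float:
    """Fold affinity gain of the multivalent construct: Kd_mono / Kd_multi."""
    return pair.kd_monomer_nm / pair.kd_multivalent_nm
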