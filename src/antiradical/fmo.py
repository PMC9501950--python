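"""Frontier-molecular-orbital bookkeeping.

HOMO/LUMO energies, the orbital gap, donor ranking by HOMO (a more positive
HOMO means a better electron donor) and a concordance check of that ranking
against ionization-potential ordering (low I should track high HOMO).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, List, Optional, Sequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrontierOrbitals:
    compound_id: str
    phase: str = "gas"
    homo: Optional[float] = None  # eV
    lumo: Optional[float] = None  # eV

    @property
    def gap(self) -> Optional[float]:
        if self.homo is None or self.lumo is None:
            return None
        return self.lumo - self.homo

    @property
    def inconsistent(self) -> bool:
        """LUMO below HOMO: flagged, not rejected."""
        g = self.gap
        return g is not None and g < 0


def orbital_gap(homo: float, lumo: float) -> float:
    """gap = LUMO - HOMO (eV); a negative result is logged as inconsistent."""
    if not (math.isfinite(homo) and math.isfinite(lumo)):
        raise ValueError("orbital energies must be finite")
    gap = lumo - homo
    if gap < 0:
        log.warning("negative orbital gap %.4f eV: LUMO below HOMO", gap)
    return gap


def rank_by_homo(orbitals: Iterable[FrontierOrbitals]) -> List[FrontierOrbitals]:
    """Stable descending order by HOMO; ties broken by compound_id.

    Entries without a HOMO energy are excluded with a logged notice.
    """
    included, excluded = [], []
    for orb in orbitals:
        (included if orb.homo is not None else excluded).append(orb)
    for orb in excluded:
        log.warning("rank_by_homo: %s excluded (no HOMO energy)", orb.compound_id)
    if not included:
        raise ValueError("no entries with a HOMO energy to rank")
    return sorted(included, key=lambda o: (-o.homo, o.compound_id))


@dataclass(frozen=True)
class KoopmansReport:
    """Pairwise concordance between descending-HOMO and ascending-I order."""

    concordance: float
    n_pairs: int
    n_concordant: int
    discordant_pairs: tuple

    @property
    def concordant(self) -> bool:
        return self.n_pairs == 0 or self.concordance == 1.0


def koopmans_consistency(orbitals: Sequence[FrontierOrbitals],
                         descriptors: Sequence) -> KoopmansReport:
    """Compare HOMO ranking with I ranking by exhaustive pair counting.

    A pair is concordant when a higher HOMO goes with a lower I; ties in
    either quantity are treated as compatible. Compounds missing on either
    side are ignored.
    """
    homo_by_id = {o.compound_id: o.homo for o in orbitals if o.homo is not None}
    i_by_id = {d.compound_id: d.I for d in descriptors}
    common = sorted(set(homo_by_id) & set(i_by_id))

    n_pairs = n_conc = 0
    discordant = []
    for a, b in combinations(common, 2):
        n_pairs += 1
        dh = homo_by_id[a] - homo_by_id[b]
        di = i_by_id[a] - i_by_id[b]
        # compatible: strict HOMO order opposes strict I order, or a tie
        if dh == 0 or di == 0 or (dh > 0) == (di < 0):
            n_conc += 1
        else:
            discordant.append((a, b))
    concordance = 1.0 if n_pairs == 0 else n_conc / n_pairs
    return KoopmansReport(concordance=concordance, n_pairs=n_pairs,
                          n_concordant=n_conc,
                          discordant_pairs=tuple(discordant))
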