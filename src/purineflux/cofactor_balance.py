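"""NADH + FADH2 ("XADH") formation from a flux distribution.

Five catabolic reactions supply the lumped reducing-equivalent pool:
glyceraldehyde 3-phosphate dehydrogenase, pyruvate dehydrogenase,
alpha-ketoglutarate dehydrogenase and malate dehydrogenase (NADH) plus
succinate dehydrogenase (FADH2).  An anabolic NADH contribution of
3.2 mmol per g CDW is converted to the percent-of-uptake scale through
the biomass yield (mmol NADH per mmol glucose x 100).
"""

from __future__ import annotations

from dataclasses import dataclass

from .network_model import FluxVector

#: anabolically derived NADH, mmol per g cell dry weight
DEFAULT_ANABOLIC_NADH = 3.2

#: XADH-supplying reactions: report label -> bundled-network reaction id
XADH_REACTIONS = {
    "GAP-DH": "gapdh",
    "Pyr-DH": "pdh",
    "AKG-DH": "akgdh",
    "MAL-DH": "mdh",
    "SUCC-DH": "sdh",
}


@dataclass
class XadhReport:
    """XADH formation in % of glucose uptake."""

    contributions: dict[str, float]
    anabolic: float

    @property
    def total(self) -> float:
        return sum(self.contributions.values()) + self.anabolic


def compute_xadh(
    fluxes: FluxVector,
    mu: float,
    y_xs: float,
    anabolic_nadh: float = DEFAULT_ANABOLIC_NADH,
    reaction_ids: dict[str, str] | None = None,
) -> XadhReport:
    """XADH formation report for one strain.

    ``fluxes`` is on the percent-of-uptake scale; ``y_xs`` (g CDW per mmol
    glucose) converts the anabolic NADH demand to the same scale.  ``mu``
    is accepted for interface symmetry with the growth parameters; the
    anabolic term mu * anabolic_nadh / q_S * 100 reduces to
    anabolic_nadh * y_xs * 100.
    """
    ids = dict(XADH_REACTIONS)
    if reaction_ids:
        ids.update(reaction_ids)
    contributions = {}
    for label, rxn_id in ids.items():
        if rxn_id not in fluxes.net:
            raise KeyError(f"flux distribution lacks reaction {rxn_id} ({label})")
        contributions[label] = fluxes.net[rxn_id]
    return XadhReport(contributions, anabolic_nadh * y_xs * 100.0)
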