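"""gliomaquant: quantitative image analysis for glioma cell-culture assays.

Four quantification stages — nuclear/cytoplasmic immunofluorescence
intensity, SAβGal positive-area scoring, whole-well neurosphere detection
and sizing, and projected-additive (Bliss-style) drug-synergy
classification — plus a synthetic-data module that renders every input
class with exact ground truth.
"""

from .frames import ColorFrame, IntensityFrame
from .config import RunConfig, load_config, save_config
from .ifquant import (CompartmentIntensity, CompartmentMasks, SetSummary,
                      quantify_frame, segment_cytoplasm, segment_nuclei,
                      summarize_set)
from .sabgal import (HUE_MAX, HUE_MIN, SabgalResult, sabgal_fraction,
                     sabgal_positive_mask, segment_cells_brightfield,
                     summarize_condition)
from .spheres import (SphereCandidate, SphereRecord, SphereSummary, WellMask,
                      analyze_well, correct_illumination, detect_spheres,
                      detect_well_interior, enhance_contrast, filter_spheres,
                      summarize_well)
from .synergy import (SynergyCall, classify_interaction, normalize_viability,
                      projected_additive, report_to_frame, synergy_report)
from . import synth

__version__ = "0.1.0"

__all__ = [
    "IntensityFrame", "ColorFrame", "RunConfig", "load_config", "save_config",
    "CompartmentMasks", "CompartmentIntensity", "SetSummary",
    "segment_nuclei", "segment_cytoplasm", "quantify_frame", "summarize_set",
    "HUE_MIN", "HUE_MAX", "SabgalResult", "segment_cells_brightfield",
    "sabgal_positive_mask", "sabgal_fraction", "summarize_condition",
    "WellMask", "SphereCandidate", "SphereRecord", "SphereSummary",
    "detect_well_interior", "correct_illumination", "enhance_contrast",
    "detect_spheres", "filter_spheres", "summarize_well", "analyze_well",
    "SynergyCall", "normalize_viability", "projected_additive",
    "classify_interaction", "synergy_report", "report_to_frame",
    "synth",
]
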