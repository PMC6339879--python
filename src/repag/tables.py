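"""Published cross-species reference values for the alternative-exon survey.

The twenty species most significantly enriched for alternative exons
downstream of G-tract acceptors (ten metazoan, ten plant), as reported:
``a`` is the percent of alternative exons transcriptome-wide, ``b`` the
number of G-tract acceptors entering the test, ``c`` the percent of
alternative exons immediately downstream of those acceptors, ``d`` the
reported fold c/a (2 decimals) and ``p`` the reported hypergeometric
p-value.  Used to verify the fold arithmetic of
:func:`repag.exon_usage.alt_exon_enrichment`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["TOP_ENRICHED_SPECIES"]

_ROWS = [
    # division, genus, species, a, b, c, d, p
    ("metazoa", "Aotus", "nancymaae", 62.3, 2695, 86.9, 1.39, 5.40e-181),
    ("metazoa", "Pan", "troglodytes", 65.8, 2518, 90.2, 1.37, 1.47e-180),
    ("metazoa", "Papio", "anubis", 62.8, 2484, 87.8, 1.40, 2.41e-175),
    ("metazoa", "Callithrix", "jacchus", 65.2, 1975, 91.1, 1.40, 4.48e-161),
    ("metazoa", "Rhinopithecus", "bieti", 65.9, 2662, 88.4, 1.34, 4.40e-159),
    ("metazoa", "Macaca", "mulatto", 71.1, 2756, 91.6, 1.29, 1.00e-157),
    ("metazoa", "Cercocebus", "atys", 64.2, 2376, 87.9, 1.37, 8.78e-154),
    ("metazoa", "Rhinopithecus", "roxellana", 64.0, 2185, 88.3, 1.38, 4.63e-148),
    ("metazoa", "Macaca", "nemestrina", 64.4, 2394, 87.3, 1.36, 5.57e-144),
    ("metazoa", "Mandrillus", "leucophaeus", 66.4, 2230, 89.2, 1.34, 3.25e-140),
    ("plants", "Triticum", "aestivum", 70.3, 5908, 83.9, 1.19, 4.47e-131),
    ("plants", "Gossypium", "raimondii", 63.4, 2110, 79.1, 1.25, 7.14e-56),
    ("plants", "Oryza", "rufipogon", 76.9, 2317, 88.3, 1.15, 9.54e-46),
    ("plants", "Glycine", "max", 68.2, 2558, 80.2, 1.18, 4.10e-43),
    ("plants", "Oryza", "glumaepatula", 76.1, 2287, 87.5, 1.15, 4.12e-43),
    ("plants", "Oryza", "nivara", 75.3, 2267, 86.8, 1.15, 9.79e-43),
    ("plants", "Oryza", "meridionalis", 77.3, 2056, 88.0, 1.14, 1.54e-36),
    ("plants", "Oryza", "barthii", 80.4, 2089, 89.9, 1.12, 1.34e-33),
    ("plants", "Zea", "mays", 83.6, 2281, 92.0, 1.10, 7.73e-33),
    ("plants", "Oryza", "punctata", 75.2, 1994, 84.0, 1.12, 4.55e-22),
]

TOP_ENRICHED_SPECIES = pd.DataFrame(
    _ROWS, columns=["division", "genus", "species", "a", "b", "c", "d", "p"]
)
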