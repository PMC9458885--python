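"""Published benchmark summaries for a resequenced 122-variety rice DUS panel.

Two small reference tables are bundled so the aggregate statistics of the
benchmark study design can be recomputed without access to the original
(undeposited) genotype and phenotype data:

* the genome-wide prediction accuracy reported for each of the 30
  standard rice DUS traits (correlation of rrBLUP-predicted vs observed
  grade codes over 100 random 90/32 train/test splits), and
* the per-chromosome SNP counts and chromosome lengths of the filtered
  ~38k-SNP panel used for molecular distances.
"""

from __future__ import annotations

#: Mean rrBLUP prediction accuracy per DUS trait (trait name, accuracy).
TRAIT_PREDICTION_ACCURACIES: list[tuple[str, float]] = [
    ("Basal leaf sheath: anthocyanin coloration", 0.129),
    ("Plant: growth habit", 0.760),
    ("Leaf blade: intensity of green color", 0.102),
    ("Leaf blade: anthocyanin coloration", 0.232),
    ("Leaf blade: pubescence", 0.447),
    ("Time of panicle emergence", 0.765),
    ("Awn: length", 0.307),
    ("Lemma: color of tip", 0.384),
    ("Stigma: color", 0.307),
    ("Stem: anthocyanin coloration of nodes", 0.354),
    ("Lemma: pubescence", 0.648),
    ("Flag leaf: attitude of blade", 0.563),
    ("Panicle: attitude", 0.614),
    ("Panicle: number of secondary branches", 0.441),
    ("Panicle: attitude of branches", 0.439),
    ("Panicle: exsertion", 0.608),
    ("Glume: length", 0.186),
    ("Lemma: color", 0.540),
    ("Grain: ratio length/width", 0.565),
    ("Grain: color", 0.360),
    ("Grain: aroma", 0.287),
    ("Plant: number of panicles", 0.315),
    ("Stem: thickness", 0.817),
    ("Stem: length", 0.840),
    ("Flag leaf: length of blade", 0.378),
    ("Flag leaf: width of blade", 0.740),
    ("Panicle: length", 0.760),
    ("1000 seed weight", 0.443),
    ("Grain: length", 0.605),
    ("Grain: width", 0.433),
]

#: Per-chromosome (length in Mb, SNP count) of the filtered marker panel.
CHROMOSOME_SNP_PANEL: dict[str, tuple[float, int]] = {
    "Chr.1": (44.36, 3822),
    "Chr.2": (37.76, 3366),
    "Chr.3": (39.69, 1959),
    "Chr.4": (35.85, 4582),
    "Chr.5": (31.24, 1770),
    "Chr.6": (32.47, 2490),
    "Chr.7": (30.28, 2976),
    "Chr.8": (29.95, 3517),
    "Chr.9": (24.76, 1946),
    "Chr.10": (25.58, 3412),
    "Chr.11": (31.78, 5126),
    "Chr.12": (26.60, 2963),
}

#: Accuracy threshold splitting traits into low (A) / high (B) groups.
DEFAULT_ACCURACY_THRESHOLD = 0.443
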