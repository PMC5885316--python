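"""Printed profiles of 26 published multi-locus phylogenetic data sets.

A survey of empirical supermatrix studies (57-7000 taxa, 5-1122 loci,
coverage densities 0.06-0.98) reported, for each data set, the taxon and
locus counts, coverage density, terrace size, strict-consensus resolution,
the decisiveness bound k_min at p = 0.05, and gene sampling sufficiency
zeta.  Those printed values are carried here verbatim as regression inputs:
the diagnostics in :mod:`.decisiveness` should reproduce them from the
printed (n, d, k) alone.

Caveats observed when transcribing:

* several printed k_min values (Birds, Scincid lizards, Ficus among them)
  are not reproducible from the *rounded* printed densities — the survey
  evidently used unrounded densities — so k_min regressions compare printed
  k against printed k_min, not recomputed k_min, except for the rows known
  to reproduce;
* a handful of terrace sizes could not be transcribed unambiguously and are
  stored as None; no computation here depends on them.

The model-choice table compares edge-linked (EL) and edge-unlinked (EUL)
partitioned likelihood fits per data set; log-likelihoods and AICs are as
printed (the printed log-likelihoods are independently rounded, so AIC is
taken from the printed AIC columns, not recomputed from lnL).
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["SurveyRow", "ModelRow", "SURVEY", "MODEL_CHOICE"]


class SurveyRow(NamedTuple):
    name: str
    n_taxa: int
    n_loci: int
    n_sites: int
    density: float           # printed, 2 decimals
    terrace_size: str | None  # printed rendering; None if ambiguous/terminated
    rho: float | None         # strict-consensus resolution; None if not run
    kmin_printed: int         # printed k_min at p = 0.05
    zeta_printed: float       # printed gene sampling sufficiency


SURVEY: tuple[SurveyRow, ...] = (
    SurveyRow("Birds",            7000,   32,  39_611, 0.12, "1.30E+388", None, 129_035,  -8.30),
    SurveyRow("Lichenized fungi", 1317,    9,   7_433, 0.44, "11,655",    None,     574,  -4.16),
    SurveyRow("Saxifragales",      946,   51,  48_242, 0.06, None,        None, 2_107_107, -10.63),
    SurveyRow("Bats",              815,   29,  20_364, 0.15, "1.43E+41",  0.78,  44_209,  -7.33),
    SurveyRow("Rosaceae",          529,    7,  11_728, 0.30, "1.72E+23",  0.77,   2_627,  -5.93),
    SurveyRow("Primates",          372,   79,  61_198, 0.37, "70.8 million", 0.92,   982,  -2.52),
    SurveyRow("Caryophyllaceae",   225,    7,  11_753, 0.29, None,        0.77,   2_349,  -5.82),
    SurveyRow("Scincid lizards",   213,    6,   5_283, 0.78, "3",         1.00,      37,  -1.83),
    SurveyRow("Chameleons",        202,    6,   5_054, 0.92, "1",         1.00,      14,  -0.83),
    SurveyRow("Solanum",           187,    7,  11_875, 0.31, None,        0.68,   1_730,  -5.51),
    SurveyRow("Primula",           185,    6,   9_408, 0.43, "2835",      0.92,     466,  -4.35),
    SurveyRow("Ranunculus",        170,    7,   9_504, 0.31, "3",         0.99,   1_889,  -5.60),
    SurveyRow("Mammals",           169,   26,  35_600, 0.94, "1",         1.00,      11,   0.86),
    SurveyRow("Insects",           144,  479, 413_459, 0.95, "1",         1.00,      10,   3.88),
    SurveyRow("Iris",              137,    6,   8_098, 0.33, "1",         1.00,   1_384,  -5.44),
    SurveyRow("Eucalyptus",        136,    6,   7_512, 0.23, "27",        0.90,   5_416,  -6.81),
    SurveyRow("Asplenium",         133,    6,   9_797, 0.21, "95",        0.64,   8_269,  -7.23),
    SurveyRow("Euphorbia",         131,    7,  11_648, 0.28, "759",       0.87,   2_681,  -5.95),
    SurveyRow("Rhododendron",      117,    7,   9_536, 0.35, "81",        0.95,   1_034,  -5.00),
    SurveyRow("Ficus",             112,    5,   5_645, 0.36, "851,445",   0.80,  12_357,  -7.81),
    SurveyRow("Syzygium",          106,    5,   5_775, 0.35, "45",        0.96,     994,  -5.29),
    SurveyRow("1000 Plants.1",     102,    8, 290_719, 0.97, "1",         1.00,       7,   0.15),
    SurveyRow("1000 Plants.2",     102,  620, 290_719, 0.91, "1",         1.00,      13,   3.88),
    SurveyRow("Caryophyllales.1",   95,  209,  87_082, 0.98, "1",         0.99,       8,   3.23),
    SurveyRow("Caryophyllales.2",   95, 1122, 504_850, 0.92, "1",         0.99,      12,   4.56),
    SurveyRow("Allium",             57,    6,   6_938, 0.24, "973,215",   0.32,   4_231,  -6.56),
)


class ModelRow(NamedTuple):
    name: str
    n_taxa: int
    density: float
    n_loci: int          # loci used in the model fits (a few rows drop loci)
    el_parameters: int
    el_lnl: float        # printed (rounded) log-likelihood
    el_aic: float        # printed AIC
    eul_parameters: int
    eul_lnl: float
    eul_aic: float

    @property
    def delta_aic(self) -> float:
        """AIC[EL] - AIC[EUL] from the printed AIC columns; positive favors
        the edge-unlinked model."""
        return self.el_aic - self.eul_aic


MODEL_CHOICE: tuple[ModelRow, ...] = (
    ModelRow("Insects",           144, 0.95,  472,    757, -30_914_676, 61_830_867, 134_992, -30_571_795, 61_413_574),
    ModelRow("Caryophyllales.2",   95, 0.92, 1120,   1307, -20_001_090, 40_004_795, 210_560, -19_699_432, 39_819_984),
    ModelRow("1000 Plants.2",     102, 0.91,  620,   5781,  -8_873_326, 17_758_215, 130_200,  -8_680_687, 17_621_773),
    ModelRow("1000 Plants.1",     102, 0.97,    8,    273,  -8_881_093, 17_762_731,   1680,  -8_857_910, 17_719_179),
    ModelRow("Caryophyllales.1",   95, 0.98,  209,    396,  -3_490_762,  6_982_316,  39_292,  -3_436_611,  6_951_806),
    ModelRow("Mammals",           169, 0.94,   26,    569,  -1_227_939,  2_457_016,   8944,  -1_210_492,  2_438_871),
    ModelRow("Chameleons",        202, 0.92,    6,    455,    -188_780,    378_471,   2460,    -184_493,    373_906),
    ModelRow("Scincid lizards",   213, 0.78,    6,    477,    -129_669,    260_291,   2592,    -126_849,    258_881),
    ModelRow("Euphorbia",         131, 0.28,    7,    322,     -46_304,     93_252,   1876,     -44_533,     92_817),
    ModelRow("Iris",              137, 0.33,    6,    311,     -29_602,     59_827,   1596,     -28_340,     59_872),
    ModelRow("Allium",             57, 0.24,    6,    155,     -15_288,     30_886,    660,     -14_891,     31_102),
    ModelRow("Primula",           185, 0.43,    6,    421,     -43_494,     87_831,   2256,     -42_060,     88_631),
    ModelRow("Ficus",             112, 0.36,    5,    264,     -14_185,     28_897,   1140,     -13_790,     29_860),
    ModelRow("Syzygium",          106, 0.35,    5,    254,     -14_557,     29_622,   1090,     -14_264,     30_707),
    ModelRow("Solanum",           187, 0.31,    7,    434,     -39_049,     78_967,   2660,     -37_528,     80_376),
    ModelRow("Caryophyllaceae",   225, 0.29,    7,    498,     -67_977,    136_951,   3108,     -66_177,    138_570),
    ModelRow("Asplenium",         133, 0.21,    6,    317,     -29_688,     60_010,   1632,     -29_252,     61_768),
    ModelRow("Eucalyptus",        136, 0.23,    6,    309,     -14_683,     29_984,   1584,     -14_324,     31_816),
    ModelRow("Ranunculus",        170, 0.31,    7,    400,     -32_738,     66_276,   2422,     -31_709,     68_262),
    ModelRow("Rhododendron",      117, 0.35,    7,    294,     -22_049,     44_687,   1680,     -21_676,     46_712),
    ModelRow("Rosaceae",          529, 0.30,    7,   1118,     -83_932,    170_101,   7448,     -80_777,    176_451),
    ModelRow("Lichenized fungi", 1317, 0.44,    9,   2712,    -499_157,  1_003_737,  23_760,    -482_238,  1_011_997),
    ModelRow("Primates",          372, 0.37,   79,   1452,    -648_012,  1_298_927,  59_250,    -611_086,  1_340_672),
    ModelRow("Bats",              815, 0.15,   29,   1888,    -589_602,  1_182_979,  47_444,    -569_791,  1_234_470),
    ModelRow("Saxifragales",      946, 0.06,   51,   2348,    -277_272,    559_240,  96_798,    -268_660,    730_917),
    ModelRow("Birds",            7000, 0.12,   32, 14_285,  -4_181_534,  8_391_639, 448_192,  -4_100_005,  9_096_394),
)
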