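"""Recurrently altered genomic regions in prostate cancer.

Two catalogues live here:

* :data:`EVENT_CATALOGUE` — the generative event model used by the synthetic
  cohort simulator.  Each event is a contiguous genomic span with a direction
  (loss/gain), a coarse evolutionary stage (early / intermediate / late) and a
  sampling weight.  Early events are predominantly segmental losses (8p, 13q,
  16q); intermediate events are focal tumour-suppressor losses (PTEN, TP53,
  RB1); late events include 5q21 loss (CHD1) and the 8q gains (cMYC).
* :data:`REGION_CATALOGUE` — the named loci used by the cohort-level region
  analyses (carrier frequencies, KS association, within-patient prevalence),
  labelled ``chrom:startMb-endMb (cytoband)`` style.

Coordinates are GRCh37 Mb, converted to bp/bin spans against a
:class:`~cnburden.genome.GenomeBins` frame at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import GenomeBins

LOSS, NEUTRAL, GAIN = -1, 0, 1

STAGES = ("early", "intermediate", "late")


@dataclass(frozen=True)
class RegionEvent:
    """A sampleable copy-number event for the synthetic cohort generator."""

    label: str
    chrom: str
    start_mb: float
    end_mb: float
    direction: int          # LOSS or GAIN
    stage: str              # early | intermediate | late
    base_weight: float

    def bin_span(self, bins: GenomeBins) -> tuple[int, int]:
        return bins.bin_span(self.chrom, int(self.start_mb * 1e6), int(self.end_mb * 1e6))

    @property
    def size_mb(self) -> float:
        return self.end_mb - self.start_mb


def _ev(label, chrom, s, e, direction, stage, w):
    return RegionEvent(label, str(chrom), s, e, direction, stage, w)


#: Generative event catalogue.  Loss and gain spans never overlap, so a truth
#: profile's bin states are unambiguous.
EVENT_CATALOGUE: tuple[RegionEvent, ...] = (
    # -- early: predominantly segmental losses, truncal by construction
    _ev("8p23_loss", 8, 6.0, 12.5, LOSS, "early", 1.0),
    _ev("8p22_loss", 8, 12.5, 19.0, LOSS, "early", 0.9),
    _ev("8p21_loss", 8, 19.0, 30.0, LOSS, "early", 1.0),
    _ev("13q_loss", 13, 32.0, 115.0, LOSS, "early", 0.8),
    _ev("16q_loss", 16, 47.0, 90.0, LOSS, "early", 0.8),
    _ev("6q_loss", 6, 62.0, 171.0, LOSS, "early", 0.7),
    _ev("2q_loss", 2, 135.0, 240.0, LOSS, "early", 0.5),
    # -- intermediate: focal tumour-suppressor losses, first gains appear
    _ev("10q23_loss", 10, 85.0, 95.0, LOSS, "intermediate", 0.9),
    _ev("17p13_loss", 17, 0.5, 10.0, LOSS, "intermediate", 0.9),
    _ev("13q14_loss", 13, 45.0, 55.0, LOSS, "intermediate", 0.9),
    _ev("21q22_loss", 21, 39.0, 43.0, LOSS, "intermediate", 0.7),
    _ev("12p13_loss", 12, 10.0, 15.0, LOSS, "intermediate", 0.4),
    _ev("18q_loss", 18, 30.0, 78.0, LOSS, "intermediate", 0.7),
    _ev("9p21_loss", 9, 20.0, 25.0, LOSS, "intermediate", 0.4),
    _ev("3p13_loss", 3, 70.0, 80.0, LOSS, "intermediate", 0.3),
    _ev("16p13_loss", 16, 5.0, 12.0, LOSS, "intermediate", 0.3),
    _ev("10q26_loss", 10, 120.0, 135.0, LOSS, "intermediate", 0.3),
    _ev("22q_loss", 22, 17.0, 51.0, LOSS, "intermediate", 0.5),
    _ev("7p_gain", 7, 0.5, 58.0, GAIN, "intermediate", 0.3),
    _ev("9q34_gain", 9, 100.0, 140.0, GAIN, "intermediate", 0.2),
    # -- late: 5q21 loss and the 8q gains, plus broad arm-level gains
    _ev("5q21_loss", 5, 90.0, 115.0, LOSS, "late", 0.9),
    _ev("4q_loss", 4, 50.0, 191.0, LOSS, "late", 0.5),
    _ev("2p_gain", 2, 10.0, 90.0, GAIN, "late", 0.4),
    _ev("8q21_gain", 8, 80.0, 110.0, GAIN, "late", 0.8),
    _ev("8q23_gain", 8, 110.0, 146.0, GAIN, "late", 1.0),
    _ev("3q_gain", 3, 150.0, 198.0, GAIN, "late", 0.4),
    _ev("7q_gain", 7, 60.0, 159.0, GAIN, "late", 0.6),
    _ev("1q_gain", 1, 145.0, 249.0, GAIN, "late", 0.5),
    _ev("20q_gain", 20, 30.0, 63.0, GAIN, "late", 0.4),
    _ev("5p_gain", 5, 0.5, 46.0, GAIN, "late", 0.3),
)


@dataclass(frozen=True)
class Region:
    """A named locus tested in the cohort-level region analyses."""

    label: str
    chrom: str
    start_mb: float
    end_mb: float
    direction: int

    def bin_span(self, bins: GenomeBins) -> tuple[int, int]:
        return bins.bin_span(self.chrom, int(self.start_mb * 1e6), int(self.end_mb * 1e6))


def _rg(label, chrom, s, e, d):
    return Region(label, str(chrom), s, e, d)


#: Named loci: focal 500-kb-scale spans around known prostate-cancer genes
#: plus cytoband-scale spans.  A core carries a region alteration iff at
#: least one called segment of matching direction overlaps >= 1 bin.
REGION_CATALOGUE: tuple[Region, ...] = (
    _rg("8:11.5-12 (8p23)", 8, 11.5, 12.0, LOSS),
    _rg("8:13-13.5 (8p22)", 8, 13.0, 13.5, LOSS),
    _rg("8:23.4-24 (8p21, NKX3.1)", 8, 23.4, 24.0, LOSS),
    _rg("10:89.5-90 (10q23, PTEN)", 10, 89.5, 90.0, LOSS),
    _rg("13:48.5-49 (13q14, RB1)", 13, 48.5, 49.0, LOSS),
    _rg("17:7.5-8 (17p13, TP53)", 17, 7.5, 8.0, LOSS),
    _rg("5:98-98.5 (5q21, CHD1)", 5, 98.0, 98.5, LOSS),
    _rg("8:128.5-129 (8q24, cMYC)", 8, 128.5, 129.0, GAIN),
    _rg("5q21-22", 5, 92.0, 115.0, LOSS),
    _rg("8q21-24", 8, 78.0, 146.0, GAIN),
    _rg("8p21-23", 8, 6.0, 30.0, LOSS),
)

#: Regions whose generating events are early-stage (used by the ordered-
#: accumulation structure checks) vs late-stage.
EARLY_REGION_LABELS = ("8:11.5-12 (8p23)", "8:13-13.5 (8p22)", "8:23.4-24 (8p21, NKX3.1)", "8p21-23")
LATE_REGION_LABELS = ("5:98-98.5 (5q21, CHD1)", "8:128.5-129 (8q24, cMYC)", "5q21-22", "8q21-24")
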