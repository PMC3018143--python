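"""Published survey numbers used for desk-scale reproduction checks.

These are the type counts and sequencing totals from the Nile tilapia
BAC-end-sequencing survey against the stickleback, medaka and Tetraodon
genome assemblies that this package re-implements the analysis of.  They
serve as fixed inputs: the ratio estimators are run on the printed type
counts and the results compared to the printed ratio columns.

Two kinds of internal inconsistency in the printed table are flagged
rather than silently patched:

* the stickleback Broad and Combined ratio cells do not follow from their
  own printed counts at all (``consistent=False``);
* three cells (the medaka Combined, Tetraodon Genoscope and Tetraodon
  Broad discordance ratios) were printed with the last digit truncated
  instead of rounded (``truncated=True``); recomputation under standard
  rounding lands one unit of the last decimal above them.
"""
from __future__ import annotations

from dataclasses import dataclass

from .classify import TypeCounts

# worked-arithmetic constants of the survey
INSERT_BP = 150_000
HIT_RATE = 0.17
OBSERVED_DOUBLE_HIT = 0.037
GENES_PER_CHROMOSOME = 1_250
PARALOG_LOSS_FRACTION = 0.05
MEAN_CHROMOSOME_BP = 48_000_000
GENOME_BP = 1_000_000_000


@dataclass(frozen=True)
class PrintedRatio:
    value: float
    consistent: bool = True   # follows from the printed counts
    truncated: bool = False   # printed with a truncated (not rounded) last digit


@dataclass(frozen=True)
class Table1Row:
    target: str
    library: str
    bacs_one_end: int
    bacs_both_ends: int
    sequences_with_hit: int
    bacs_with_hit: int
    counts: TypeCounts
    intra: PrintedRatio
    discordant: PrintedRatio


def _row(target, library, one, both, seq_hit, bac_hit, n1, n2, n3, n4,
         intra, disc) -> Table1Row:
    return Table1Row(
        target=target, library=library,
        bacs_one_end=one, bacs_both_ends=both,
        sequences_with_hit=seq_hit, bacs_with_hit=bac_hit,
        counts=TypeCounts(
            library=library, target=target, n1=n1, n2=n2, n3=n3, n4=n4,
            ends_with_hit=seq_hit, bacs_with_hit=bac_hit,
        ),
        intra=intra, discordant=disc,
    )


TABLE1: list[Table1Row] = [
    _row("stickleback", "Genoscope", 6_734, 30_649, 11_229, 10_048,
         7_987, 797, 54, 153,
         PrintedRatio(0.063), PrintedRatio(0.206)),
    _row("stickleback", "Broad", 12_758, 56_118, 21_754, 19_510,
         14_405, 1_416, 142, 633,
         PrintedRatio(0.054, consistent=False), PrintedRatio(0.286, consistent=False)),
    _row("stickleback", "Combined", 19_492, 86_767, 33_053, 29_558,
         22_392, 2_213, 196, 786,
         PrintedRatio(0.057, consistent=False), PrintedRatio(0.259, consistent=False)),
    _row("medaka", "Genoscope", 6_734, 30_649, 9_764, 9_278,
         7_087, 469, 43, 226,
         PrintedRatio(0.084), PrintedRatio(0.364)),
    _row("medaka", "Broad", 12_758, 56_118, 19_699, 17_943,
         13_907, 886, 51, 624,
         PrintedRatio(0.054), PrintedRatio(0.432)),
    _row("medaka", "Combined", 19_492, 86_767, 29_463, 27_221,
         20_994, 1_355, 94, 850,
         PrintedRatio(0.065), PrintedRatio(0.410, truncated=True)),
    _row("Tetraodon", "Genoscope", 6_734, 30_649, 6_931, 6_386,
         3_879, 265, 14, 62,
         PrintedRatio(0.050), PrintedRatio(0.222, truncated=True)),
    _row("Tetraodon", "Broad", 12_758, 56_118, 14_260, 13_227,
         7_279, 503, 19, 188,
         PrintedRatio(0.036), PrintedRatio(0.291, truncated=True)),
    _row("Tetraodon", "Combined", 19_492, 86_767, 21_191, 19_613,
         11_158, 768, 33, 250,
         PrintedRatio(0.041), PrintedRatio(0.269)),
]


def get_row(target: str, library: str) -> Table1Row:
    for row in TABLE1:
        if row.target == target and row.library == library:
            return row
    raise KeyError(f"no published row for {target}/{library}")


@dataclass(frozen=True)
class LibrarySequencing:
    """Published per-centre sequencing totals (post quality trimming)."""

    name: str
    n_clones: int
    mean_insert_bp: int
    n_sequences: int
    total_bp: int
    printed_mean_length: float
    printed_clone_coverage: float | None = None
    printed_sequence_coverage: float | None = None


GENOSCOPE = LibrarySequencing(
    name="Genoscope", n_clones=37_383, mean_insert_bp=182_000,
    n_sequences=68_032, total_bp=38_272_386,
    printed_mean_length=562.6,
    printed_clone_coverage=6.8, printed_sequence_coverage=0.038,
)

BROAD = LibrarySequencing(
    name="Broad", n_clones=68_876, mean_insert_bp=150_000,
    n_sequences=124_995, total_bp=65_912_624,
    printed_mean_length=527.3,
    printed_sequence_coverage=0.066,
)
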