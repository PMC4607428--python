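"""Curated coordinates of reported S. cerevisiae splicing events (SGD R64-1-1).

Published coordinates of novel introns, alternative 3' splice sites and
terminal introns in the yeast genome, usable as worked examples for the
coordinate arithmetic, frame-rule and classification operations without any
external download.  All coordinates are 1-based inclusive on the given
chromosome; lengths satisfy ``length == end - start + 1``; alternative-site
distances are signed (positive = intron extended past the canonical site).
"""

from __future__ import annotations

import pandas as pd

_COLS_LEN = ["chrom", "strand", "start", "end", "length", "support", "gene"]
_COLS_DIST = ["chrom", "strand", "start", "end", "distance", "support", "gene"]

#: Novel CDS introns whose length is a multiple of 3 (frame preserving).
NOVEL_FRAME_PRESERVING = pd.DataFrame(
    [
        ("VII", "-", 883015, 883140, 126, 291, "YGR192C"),
        ("VII", "-", 253186, 253248, 63, 66, "YGL136C"),
        ("VI", "+", 107341, 107442, 102, 50, "YFL014W"),
        ("XI", "+", 220778, 220831, 54, 43, "YKL117W"),
        ("IV", "+", 600933, 601031, 99, 41, "YDR077W"),
        ("VIII", "-", 33627, 33698, 72, 25, "YHL034C"),
        ("VII", "-", 437563, 437628, 66, 23, "YGL031C"),
        ("VI", "-", 220902, 221108, 207, 13, "YFR031C-A"),
    ],
    columns=_COLS_LEN,
)

#: Novel CDS introns that shift the reading frame.
NOVEL_FRAME_DISRUPTING = pd.DataFrame(
    [
        ("VII", "+", 439382, 439479, 98, 56, "YGL030W"),
        ("XII", "+", 1073669, 1073966, 298, 41, "YLR467W"),
        ("XV", "+", 1086634, 1086931, 298, 36, "YOR396W"),
        ("IV", "+", 1527482, 1527779, 298, 35, "YDR545W"),
    ],
    columns=_COLS_LEN,
)

#: Novel introns located in 5' untranslated regions (frame irrelevant).
NOVEL_UTR5 = pd.DataFrame(
    [
        ("XIII", "-", 4795, 4999, 205, 89, "YML133C"),
        ("XII", "+", 1072192, 1072397, 206, 76, "YLR467W"),
        ("XIV", "-", 282745, 282804, 60, 65, "YNL194C"),
        ("IV", "+", 1526005, 1526210, 206, 62, "YDR545W"),
        ("XV", "+", 1085157, 1085362, 206, 62, "YOR396W"),
        ("II", "-", 5120, 5335, 216, 50, "YBL111C"),
        ("II", "+", 691967, 692133, 167, 43, "YBR237W"),
        ("XIII", "+", 610808, 611036, 229, 41, "YMR175W"),
    ],
    columns=_COLS_LEN,
)

#: Alternative 3' splice sites at annotated introns, preserving the frame.
ALT3_FRAME_PRESERVING = pd.DataFrame(
    [
        ("XVI", "-", 5778, 5988, 63, 203, "YPL283C"),
        ("XI", "+", 155272, 155636, -18, 86, "YKL157W"),
        ("IV", "+", 652781, 653526, 3, 81, "YDR099W"),
        ("XIII", "+", 732466, 733034, 159, 39, "YMR230W"),
        ("VIII", "-", 498708, 498786, 12, 35, "YHR199C-A"),
        ("II", "+", 393181, 393507, -3, 28, "YBR078W"),
        ("XI", "-", 93303, 93465, 9, 24, "YKL186C"),
        ("XII", "+", 1067085, 1067303, -60, 22, "YLR464W"),
        ("II", "+", 653369, 653524, 72, 16, "YBR215W"),
    ],
    columns=_COLS_DIST,
)

#: Alternative 3' splice sites with frame-disruption potential.  The
#: ``region`` column separates CDS events from 5'UTR events where the frame
#: is irrelevant; distances here are magnitudes as published.
ALT3_FRAME_DISRUPTING = pd.DataFrame(
    [
        ("II", "+", 170677, 170757, 47, 81, "YBL026W", "CDS"),
        ("XI", "-", 93367, 93465, 55, 55, "YKL186C", "CDS"),
        ("IV", "-", 254956, 255044, 19, 40, "YDL115C", "CDS"),
        ("V", "-", 269784, 270148, 32, 25, "YER056C-A", "CDS"),
        ("XII", "+", 855878, 856427, 7, 300, "YLR367W", "5'UTR"),
        ("X", "-", 172413, 172752, 20, 72, "YJL130C", "5'UTR"),
        ("XVI", "+", 115219, 115298, 5, 42, "YPL230W", "5'UTR"),
    ],
    columns=_COLS_DIST + ["region"],
)

#: Novel terminal introns containing the annotated stop codon.
TERMINAL_INTRONS = pd.DataFrame(
    [
        ("II", "-", 443706, 443833, 128, 200, "YBR101C"),
        ("XIII", "+", 559783, 560157, 375, 162, "YMR147W"),
        ("VII", "+", 436313, 436374, 62, 53, "YGL033W"),
    ],
    columns=_COLS_LEN,
)


def length_tables() -> dict[str, pd.DataFrame]:
    """All curated tables that print an explicit intron Length column."""
    return {
        "novel_frame_preserving": NOVEL_FRAME_PRESERVING,
        "novel_frame_disrupting": NOVEL_FRAME_DISRUPTING,
        "novel_utr5": NOVEL_UTR5,
        "terminal_introns": TERMINAL_INTRONS,
    }


def novel_cds_introns() -> pd.DataFrame:
    """The pooled protein-coding novel introns (frame rule worked example)."""
    return pd.concat(
        [NOVEL_FRAME_PRESERVING, NOVEL_FRAME_DISRUPTING], ignore_index=True
    )
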