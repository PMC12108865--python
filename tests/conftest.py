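"""Shared fixtures: the worked basal-resting dictionary and small tables."""

import pandas as pd
import pytest

from fpcam import MarkerDictionary, MarkerTable

#: The published worked example: ten basal-resting marker genes whose votes
#: (4,4,3,2,2,2,1,1,1,1) sum to 21.
BASAL_ROWS = [
    ("Basal resting", "TP63", 4, 21),
    ("Basal resting", "KRT5", 4, 21),
    ("Basal resting", "KRT15", 3, 21),
    ("Basal resting", "FXYD3", 2, 21),
    ("Basal resting", "KRT14", 2, 21),
    ("Basal resting", "KRT17", 2, 21),
    ("Basal resting", "EPCAM", 1, 21),
    ("Basal resting", "ELF3", 1, 21),
    ("Basal resting", "IGFBP2", 1, 21),
    ("Basal resting", "SERPINF1", 1, 21),
]


@pytest.fixture
def basal_dictionary() -> MarkerDictionary:
    return MarkerDictionary(
        pd.DataFrame(BASAL_ROWS,
                     columns=["cell_type", "gene", "votes", "total_votes"])
    )


@pytest.fixture
def basal_tsv(tmp_path):
    """The worked example written with its published header names."""
    path = tmp_path / "basal.tsv"
    header = "Cell Cluster\tMarker Gene\tNumber of Votes Received\tVotes\tPercent"
    lines = [header]
    from fractions import Fraction
    for cell_type, gene, votes, total in BASAL_ROWS:
        lines.append(f"{cell_type}\t{gene}\t{votes}\t{total}"
                     f"\t{Fraction(votes, total)}")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_type_dictionary() -> MarkerDictionary:
    rows = [
        ("T_cell", "CD3D", 3, 6), ("T_cell", "CD3E", 2, 6), ("T_cell", "CD2", 1, 6),
        ("B_cell", "CD19", 2, 4), ("B_cell", "MS4A1", 2, 4),
    ]
    return MarkerDictionary(
        pd.DataFrame(rows, columns=["cell_type", "gene", "votes", "total_votes"])
    )


@pytest.fixture
def small_marker_table() -> MarkerTable:
    rows = [
        ("CD3D", "c0", 2.0), ("CD3E", "c0", 1.0),
        ("CD19", "c1", 3.0), ("MS4A1", "c1", 1.5), ("CD3D", "c1", 0.5),
    ]
    return MarkerTable(pd.DataFrame(rows, columns=["gene", "cluster", "value"]))
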