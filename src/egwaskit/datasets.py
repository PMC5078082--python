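"""Bundled example data: H3K27me3 immunostaining scores from a 92-patient
gastric cohort (grades scored -, +, ++, +++), stratified by gender, age and
tissue pathology. These are the printed clinical count tables the IHC module
is validated against."""
from __future__ import annotations

import numpy as np

from .ihc import ScoreTable

H3K27ME3_GENDER = ScoreTable(
    groups=["Male", "Female"],
    grades=["-", "+", "++", "+++"],
    counts=np.array([[12, 36, 14, 4], [9, 8, 6, 3]]),
)

H3K27ME3_AGE = ScoreTable(
    groups=["<=60", ">60"],
    grades=["-", "+", "++", "+++"],
    counts=np.array([[6, 31, 11, 7], [10, 19, 6, 2]]),
)

H3K27ME3_PATHOLOGY = ScoreTable(
    groups=["Normal", "Paracarcinoma", "Adenocarcinoma"],
    grades=["-", "+", "++", "+++"],
    counts=np.array([[0, 3, 7, 0], [0, 8, 21, 8], [0, 4, 17, 24]]),
)
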