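import numpy as np
import pytest

from aainterp.descriptors import load_bundled_database

#: Kyte & Doolittle hydropathy values, transcribed from the published scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: A well-formed single-record AAindex1 fixture (Kyte-Doolittle values in
#: the standard A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V column order).
AAINDEX1_KD_RECORD = """\
H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
R LIT:0807099b PMID:7108955
A Kyte, J. and Doolittle, R.F.
T A simple method for displaying the hydropathic character of a protein
J J. Mol. Biol. 157, 105-132 (1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
     3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7    -0.9    -1.3     4.2
//
"""

#: A record whose value block contains NA tokens (unusable as a numeric
#: descriptor and therefore skipped by the parser).
AAINDEX1_NA_RECORD = """\
H AVBF000101
D Screening coefficients gamma, local (Avbelj, 2000)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.0728  0.0394  0.0339  0.0130      NA  0.0126  0.0497  0.0734  0.0214  0.0943
    0.0815  0.0586  0.0729  0.0921  0.0925  0.0663  0.0687  0.0548  0.0516  0.0830
//
"""


@pytest.fixture(scope="session")
def db():
    return load_bundled_database()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
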