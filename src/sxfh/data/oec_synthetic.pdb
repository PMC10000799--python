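REMARK   1 SYNTHETIC stand-in for the PSII oxygen-evolving complex
REMARK   1 Mn4CaO5 geometry rebuilt from published interatomic distances;
REMARK   1 not deposited coordinates. Cell/space group per printed values.
CRYST1  122.200  228.500  286.400  90.00  90.00  90.00 P 21 21 21    4
HETATM    1 MN1  OEX A 601      20.000  35.000  50.000  1.00 20.00          MN
HETATM    2 MN2  OEX A 601      22.810  35.000  50.000  1.00 20.00          MN
HETATM    3 MN3  OEX A 601      21.824  37.738  50.000  1.00 20.00          MN
HETATM    4 MN4  OEX A 601      20.411  39.562  51.740  1.00 20.00          MN
HETATM    5 CA1  OEX A 601      21.393  35.974  52.887  1.00 20.00          CA
HETATM    6  O1  OEX A 601      21.405  35.385  51.140  1.00 20.00           O
HETATM    7  O2  OEX A 601      21.964  36.242  51.079  1.00 20.00           O
HETATM    8  O3  OEX A 601      21.545  35.913  50.900  1.00 20.00           O
HETATM    9  O4  OEX A 601      19.507  40.730  52.855  1.00 20.00           O
HETATM   10  O5  OEX A 601      20.692  39.200  49.948  1.00 20.00           O
HETATM   11 MN1  OEX B 601      45.000  80.000  95.000  1.00 20.00          MN
HETATM   12 MN2  OEX B 601      42.190  80.000  95.000  1.00 20.00          MN
HETATM   13 MN3  OEX B 601      43.176  77.262  95.000  1.00 20.00          MN
HETATM   14 MN4  OEX B 601      44.589  75.438  96.740  1.00 20.00          MN
HETATM   15 CA1  OEX B 601      43.607  79.026  97.887  1.00 20.00          CA
HETATM   16  O1  OEX B 601      43.595  79.615  96.140  1.00 20.00           O
HETATM   17  O2  OEX B 601      43.036  78.758  96.079  1.00 20.00           O
HETATM   18  O3  OEX B 601      43.455  79.087  95.900  1.00 20.00           O
HETATM   19  O4  OEX B 601      45.493  74.270  97.855  1.00 20.00           O
HETATM   20  O5  OEX B 601      44.308  75.800  94.948  1.00 20.00           O
END
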