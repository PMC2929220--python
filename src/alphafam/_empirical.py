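"""Empirical amino-acid replacement model constants.

Lower-triangular exchangeabilities (row-major, row 2 onward) and
equilibrium frequencies for the JTT (Jones, Taylor & Thornton 1992) and
Dayhoff (Dayhoff, Schwartz & Orcutt 1978) models, in the standard
A R N D C Q E G H I L K M F P S T W Y V residue order.  Values are the
published integer exchangeability tables as distributed with common
phylogenetics software (cross-checked against R phangorn's model objects).
"""

MODEL_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

JTT_EXCHANGE = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

JTT_FREQS = [
    0.07674792325, 0.05169094831, 0.04264495736, 0.05154394846,
    0.01980298020, 0.04075195925, 0.06182993817, 0.07315192685,
    0.02294397706, 0.05376094624, 0.09190390810, 0.05867594132,
    0.02382597617, 0.04012595987, 0.05090094910, 0.06876493124,
    0.05856494144, 0.01426098574, 0.03210196790, 0.06600493400,
]

DAYHOFF_EXCHANGE = [
    27, 98, 120, 36, 89, 198, 240, 23, 65, 41, 26, 72, 18, 250, 409, 371, 0,
    24, 208, 32, 0, 23, 246, 1, 9, 240, 64, 15, 464, 90, 14, 103, 154, 26,
    201, 8, 24, 905, 0, 103, 148, 139, 535, 77, 34, 318, 1, 14, 42, 495, 229,
    23, 95, 15, 0, 134, 1153, 125, 86, 24, 0, 71, 0, 0, 13, 95, 66, 0, 0, 18,
    0, 0, 11, 28, 44, 0, 0, 0, 0, 19, 161, 16, 0, 96, 49, 716, 28, 606, 18,
    73, 153, 114, 0, 153, 56, 53, 0, 0, 35, 81, 43, 61, 11, 83, 30, 0, 51,
    79, 34, 0, 22, 37, 10, 0, 7, 27, 17, 15, 34, 234, 30, 0, 0, 54, 7, 44,
    26, 0, 48, 94, 35, 22, 27, 127, 44, 257, 46, 336, 196, 12, 24, 192, 0,
    37, 889, 18, 527, 157, 32, 17, 33, 46, 28, 175, 243, 0, 33, 96, 136, 0,
    13, 10, 92, 17, 62, 104, 0, 0, 258, 11, 46, 13, 76, 698, 12, 245, 78, 0,
    0, 48, 550, 75, 34, 30, 0, 42, 157, 61, 0, 28,
]

DAYHOFF_FREQS = [
    0.08712691287, 0.04090395910, 0.04043195957, 0.04687195313,
    0.03347396653, 0.03825496175, 0.04952995047, 0.08861191139,
    0.03361796638, 0.03688596311, 0.08535691464, 0.08048191952,
    0.01475298525, 0.03977196023, 0.05067994932, 0.06957693042,
    0.05854194146, 0.01049398951, 0.02991597008, 0.06471793528,
]
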