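"""Benchmark rows from a published pediatric milk-allergy diagnostic-accuracy
study, used as a regression fixture.

Each row carries the printed 2x2 counts (TP/FP, TN/FN) and the printed
metric strings.  Cells set to ``None`` in ``expect`` are excluded from the
regression: the printed value there is not reproducible from the printed
counts under exact arithmetic with half-up rounding (double-rounded cells
such as 63.49% printed as 64%, one specificity typo of 25% for 75%, and two
count-level errata).  The row whose TP/FP and TN/FN columns are transposed
relative to its own printed specificity is omitted entirely.

Panels: A = baked-milk allergy, all ages (n 146); B = baked-milk allergy,
under 2 years (n 26); C = fresh-milk allergy, all ages (n 130); D =
fresh-milk allergy, under 2 years (n 16).  Cutoff types: se100 = 100%
sensitivity (rule-out), opt = Youden-optimal, sp100 = 100% specificity
(rule-in).
"""

# label: panel/marker/cutoff-type; counts: (tp, fp, tn, fn);
# expect keys: bal (2-dp proportion), se, sp, ppv, npv, acc (integer %).
REFERENCE_ROWS = [
    {"label": "A spt_me se100", "counts": (20, 126, 0, 0),
     "expect": {"bal": "0.50", "se": "100%", "sp": "0%", "ppv": "14%", "npv": "—", "acc": "14%"}},
    {"label": "A spt_me opt", "counts": (14, 46, 80, 6),
     "expect": {"bal": "0.67", "se": "70%", "sp": None, "ppv": "23%", "npv": "93%", "acc": "64%"}},
    {"label": "A spt_me sp100", "counts": (0, 0, 126, 20),
     "expect": {"bal": "0.50", "se": "0%", "sp": "100%", "ppv": "—", "npv": "86%", "acc": "86%"}},
    {"label": "A spt_bm se100", "counts": (20, 126, 0, 0),
     "expect": {"bal": "0.50", "se": "100%", "sp": "0%", "ppv": "14%", "npv": "—", "acc": "14%"}},
    {"label": "A spt_bm opt", "counts": (16, 31, 95, 4),
     "expect": {"bal": "0.78", "se": "80%", "sp": None, "ppv": "34%", "npv": "96%", "acc": "76%"}},
    {"label": "A spt_bm sp100", "counts": (1, 0, 126, 19),
     "expect": {"bal": "0.53", "se": "5%", "sp": "100%", "ppv": "100%", "npv": "87%", "acc": "87%"}},
    {"label": "A sige_cm se100", "counts": (20, 109, 17, 0),
     "expect": {"bal": "0.57", "se": "100%", "sp": None, "ppv": "16%", "npv": "100%", "acc": "25%"}},
    {"label": "A sige_cm opt", "counts": (18, 43, 83, 2),
     "expect": {"bal": "0.78", "se": "90%", "sp": "66%", "ppv": "30%", "npv": "98%", "acc": "69%"}},
    {"label": "A sige_cm sp100", "counts": (0, 0, 126, 20),
     "expect": {"bal": "0.50", "se": "0%", "sp": "100%", "ppv": "—", "npv": "86%", "acc": "86%"}},
    {"label": "A sige_bm se100", "counts": (20, 99, 27, 0),
     "expect": {"bal": "0.61", "se": "100%", "sp": "21%", "ppv": "17%", "npv": "100%", "acc": "32%"}},
    {"label": "A sige_bm opt", "counts": (18, 37, 89, 2),
     "expect": {"bal": "0.80", "se": "90%", "sp": "71%", "ppv": "33%", "npv": "98%", "acc": "73%"}},
    {"label": "A sige_bm sp100", "counts": (0, 0, 126, 20),
     "expect": {"bal": "0.50", "se": "0%", "sp": "100%", "ppv": "—", "npv": "86%", "acc": "86%"}},
    {"label": "A bat_me se100", "counts": (20, 92, 34, 0),
     "expect": {"bal": None, "se": "100%", "sp": "27%", "ppv": "18%", "npv": "100%", "acc": "37%"}},
    {"label": "A bat_me sp100", "counts": (1, 0, 126, 19),
     "expect": {"bal": None, "se": "5%", "sp": "100%", "ppv": "100%", "npv": "87%", "acc": "87%"}},
    {"label": "A bat_bm se100", "counts": (20, 55, 71, 0),
     "expect": {"bal": "0.78", "se": "100%", "sp": "56%", "ppv": "27%", "npv": "100%", "acc": "62%"}},
    {"label": "A bat_bm opt", "counts": (16, 13, 113, 4),
     "expect": {"bal": "0.85", "se": "80%", "sp": "90%", "ppv": "55%", "npv": "97%", "acc": "88%"}},
    {"label": "A bat_bm sp100", "counts": (3, 0, 126, 17),
     "expect": {"bal": "0.58", "se": "15%", "sp": "100%", "ppv": "100%", "npv": "88%", "acc": "88%"}},
    {"label": "B spt_me se100", "counts": (5, 21, 0, 0),
     "expect": {"bal": "0.50", "se": "100%", "sp": "0%", "ppv": "19%", "npv": "—", "acc": "19%"}},
    {"label": "B spt_me opt", "counts": (4, 8, 13, 1),
     "expect": {"bal": "0.71", "se": "80%", "sp": "62%", "ppv": "33%", "npv": "93%", "acc": "65%"}},
    {"label": "B spt_me sp100", "counts": (0, 0, 21, 5),
     "expect": {"bal": "0.50", "se": "0%", "sp": "100%", "ppv": "—", "npv": "81%", "acc": "81%"}},
    {"label": "B sige_cm se100", "counts": (5, 17, 4, 0),
     "expect": {"bal": "0.60", "se": "100%", "sp": "19%", "ppv": "23%", "npv": "100%", "acc": "35%"}},
    {"label": "B sige_cm opt", "counts": (4, 4, 17, 1),
     "expect": {"bal": None, "se": "80%", "sp": "81%", "ppv": "50%", "npv": "94%", "acc": "81%"}},
    {"label": "B sige_cm sp100", "counts": (1, 0, 21, 4),
     "expect": {"bal": "0.60", "se": "20%", "sp": "100%", "ppv": "100%", "npv": "84%", "acc": None}},
    {"label": "B bat_bm se100", "counts": (5, 5, 16, 0),
     "expect": {"bal": "0.88", "se": "100%", "sp": "76%", "ppv": "50%", "npv": "100%", "acc": "81%"}},
    {"label": "B bat_bm sp100", "counts": (3, 0, 21, 2),
     "expect": {"bal": "0.80", "se": "60%", "sp": "100%", "ppv": "100%", "npv": "91%", "acc": "92%"}},
    {"label": "C spt_me se100", "counts": (68, 62, 0, 0),
     "expect": {"bal": "0.50", "se": "100%", "sp": "0%", "ppv": "52%", "npv": "—", "acc": "52%"}},
    {"label": "C spt_me opt", "counts": (40, 8, 54, 28),
     "expect": {"bal": "0.73", "se": "59%", "sp": "87%", "ppv": "83%", "npv": "66%", "acc": "72%"}},
    {"label": "C spt_me sp100", "counts": (3, 0, 62, 65),
     "expect": {"bal": "0.52", "se": "4%", "sp": "100%", "ppv": "100%", "npv": "49%", "acc": "50%"}},
    {"label": "C sige_cm se100", "counts": (68, 56, 6, 0),
     "expect": {"bal": "0.55", "se": "100%", "sp": "10%", "ppv": "55%", "npv": "100%", "acc": "57%"}},
    {"label": "C sige_cm opt", "counts": (42, 14, 48, 26),
     "expect": {"bal": "0.70", "se": "62%", "sp": "77%", "ppv": "75%", "npv": "65%", "acc": "69%"}},
    {"label": "C sige_cm sp100", "counts": (1, 0, 62, 67),
     "expect": {"bal": "0.51", "se": None, "sp": "100%", "ppv": "100%", "npv": "48%", "acc": "48%"}},
    {"label": "C bat_cd63 se100", "counts": (68, 51, 11, 0),
     "expect": {"bal": "0.59", "se": "100%", "sp": "18%", "ppv": "57%", "npv": "100%", "acc": "61%"}},
    {"label": "C bat_cd63 opt", "counts": (48, 15, 47, 20),
     "expect": {"bal": "0.73", "se": "71%", "sp": "76%", "ppv": "76%", "npv": "70%", "acc": "73%"}},
    {"label": "C bat_cd63 sp100", "counts": (13, 0, 62, 55),
     "expect": {"bal": "0.60", "se": "19%", "sp": "100%", "ppv": "100%", "npv": "53%", "acc": "58%"}},
    {"label": "C bat_si se100", "counts": (68, 62, 0, 0),
     "expect": {"bal": "0.50", "se": "100%", "sp": "0%", "ppv": "52%", "npv": "—", "acc": "52%"}},
    {"label": "C bat_si opt", "counts": (52, 15, 47, 16),
     "expect": {"bal": "0.76", "se": None, "sp": "76%", "ppv": "78%", "npv": "75%", "acc": "76%"}},
    {"label": "C bat_si sp100", "counts": (15, 0, 62, 53),
     "expect": {"bal": "0.61", "se": "22%", "sp": "100%", "ppv": "100%", "npv": "54%", "acc": "59%"}},
    {"label": "D spt_me se100", "counts": (8, 8, 0, 0),
     "expect": {"bal": "0.50", "se": "100%", "sp": "0%", "ppv": "50%", "npv": "—", "acc": "50%"}},
    {"label": "D spt_me opt", "counts": (6, 2, 6, 2),
     "expect": {"bal": "0.75", "se": "75%", "sp": "75%", "ppv": "75%", "npv": "75%", "acc": "75%"}},
    {"label": "D spt_me sp100", "counts": (4, 0, 8, 4),
     "expect": {"bal": "0.75", "se": "50%", "sp": "100%", "ppv": "100%", "npv": "67%", "acc": "75%"}},
    {"label": "D sige_cm se100", "counts": (8, 6, 2, 0),
     "expect": {"bal": "0.63", "se": "100%", "sp": "25%", "ppv": "57%", "npv": "100%", "acc": "63%"}},
    {"label": "D sige_cm opt", "counts": (5, 2, 6, 3),
     "expect": {"bal": "0.69", "se": "63%", "sp": "75%", "ppv": "71%", "npv": "67%", "acc": "69%"}},
    {"label": "D sige_cm sp100", "counts": (2, 0, 8, 6),
     "expect": {"bal": "0.63", "se": "25%", "sp": "100%", "ppv": "100%", "npv": "57%", "acc": "63%"}},
    {"label": "D bat_cd63 se100", "counts": (8, 2, 6, 0),
     "expect": {"bal": "0.88", "se": "100%", "sp": "75%", "ppv": "80%", "npv": "100%", "acc": "88%"}},
    {"label": "D bat_cd63 opt", "counts": (7, 1, 7, 1),
     "expect": {"bal": None, "se": "88%", "sp": "88%", "ppv": "88%", "npv": "88%", "acc": "88%"}},
    {"label": "D bat_cd63 sp100", "counts": (5, 0, 8, 3),
     "expect": {"bal": "0.81", "se": "63%", "sp": "100%", "ppv": "100%", "npv": "73%", "acc": "81%"}},
]

# Two-cutoff triage benchmark: (label, tolerant, equivocal, allergic,
# ofc_negative, ofc_positive, pct_ofc, pct_ofc_positive). All rows are
# internally consistent.
REFERENCE_TRIAGE_ROWS = [
    ("all spt_me", 0, 146, 0, 126, 20, "100%", "14%"),
    ("all spt_bm", 0, 145, 1, 126, 19, "99%", "13%"),
    ("all sige_cm", 17, 129, 0, 109, 20, "88%", "16%"),
    ("all sige_bm", 27, 119, 0, 99, 20, "82%", "17%"),
    ("all bat_me", 34, 111, 1, 92, 19, "76%", "17%"),
    ("all bat_bm", 71, 72, 3, 55, 17, "49%", "24%"),
    ("under2 spt_me", 0, 26, 0, 21, 5, "100%", "19%"),
    ("under2 sige_cm", 4, 21, 1, 17, 4, "81%", "19%"),
    ("under2 bat_bm", 16, 7, 3, 5, 2, "27%", "29%"),
]

# Reported challenge-reduction figures: (equivocal, total, printed reduction)
REFERENCE_OFC_REDUCTIONS = [
    (72, 146, "51%"),
    (7, 26, "73%"),
]
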