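"""One-off generator for the bundled study-fixture TSVs."""
import csv, pathlib

out = pathlib.Path(__file__).resolve().parents[1] / "src" / "mmrscreen" / "data"

# variant_id, human_aa, mouse_aa, nt_change, insight_class, prior_label
variants = [
    # proof-of-principle polymorphisms (5)
    ("PP_N1", ".", ".", ".", "1", "non_pathogenic"),
    ("PP_N2", ".", ".", ".", "1", "non_pathogenic"),
    ("PP_N3", ".", ".", ".", "1", "non_pathogenic"),
    ("PP_N4", ".", ".", ".", "1", "non_pathogenic"),
    ("L1087R", "L1087R", "L1085R", ".", "3", "non_pathogenic"),
    # proof-of-principle pathogenic (4)
    ("V399E", "V399E", "V397E", ".", "5", "pathogenic"),
    ("L450P", "L450P", "L448P", ".", "5", "pathogenic"),
    ("G1139S", "G1139S", "G1137S", ".", "3", "pathogenic"),
    ("R1334Q", "R1334Q", "R1332Q", ".", "5", "pathogenic"),
    # 18 literature/database VUS
    ("G686D", "G686D", "G683D", ".", "4", "pathogenic"),
    ("L1063R", "L1063R", "L1060R", ".", "4", "pathogenic"),
    ("E1193K", "E1193K", "E1191K", ".", "3", "uncertain"),
    ("T1219D", "T1219D", "T1217D", ".", "3", "uncertain"),
    ("T1219I", "T1219I", "T1217I", ".", "3", "uncertain"),
    ("R128L", "R128L", ".", ".", "2", "non_pathogenic"),
    ("R468H", "R468H", ".", ".", "2", "non_pathogenic"),
    ("V509A", "V509A", ".", ".", "2", "non_pathogenic"),
    ("Y556F", "Y556F", ".", ".", "2", "non_pathogenic"),
    ("P623A", "P623A", ".", ".", "3", "uncertain"),
    ("S666P", "S666P", ".", ".", "3", "uncertain"),
    ("E983Q", "E983Q", ".", ".", "3", "uncertain"),
    ("R1095C", "R1095C", ".", ".", "3", "uncertain"),
    ("T1255M", "T1255M", ".", ".", "3", "uncertain"),
    ("R1304K", "R1304K", ".", ".", "3", "uncertain"),
    ("S285I", "S285I", ".", ".", "3", "uncertain"),
    ("G566R", "G566R", "G565R", ".", "3", "non_pathogenic"),
    ("T1142M", "T1142M", ".", ".", "3", "uncertain"),
    # 8 clinical-cohort VUS
    ("R511G", "R511G", "R510G", ".", "3", "uncertain"),
    ("A587P", "A587P", "A586P", ".", "4", "pathogenic"),
    ("F706S", "F706S", "F703S", ".", "3", "uncertain"),
    ("A25S", "A25S", ".", ".", "3", "uncertain"),
    ("E221D", "E221D", ".", ".", "3", "uncertain"),
    ("G670R", "G670R", ".", ".", "NA", "uncertain"),
    ("R922Q", "R922Q", ".", ".", "NA", "uncertain"),
    ("c.3438+6T>C", ".", ".", "c.3438+6T>C", "NA", "uncertain"),
]

with open(out / "variants.tsv", "w", newline="") as fh:
    w = csv.writer(fh, delimiter="\t", lineterminator="\n")
    w.writerow(["variant_id", "human_aa_change", "mouse_aa_change",
                "nucleotide_change", "insight_class", "prior_label"])
    w.writerows(variants)

# panel composition per variant: list of (round, n_loh, n_bg, n_mut)
NOT_DETECTED = [("antisense", 17, 1, 0), ("sense", 17, 1, 0)]
DETECTED_FULL = [("antisense", 11, 0, 7)]
panels = {}
for vid, *_ in variants:
    panels[vid] = NOT_DETECTED
for vid in ("V399E", "L450P", "R1334Q", "G686D", "L1063R",
            "E1193K", "T1219D", "T1219I", "A587P"):
    panels[vid] = DETECTED_FULL
panels["G1139S"] = [("antisense", 11, 1, 6)]   # the single background colony
panels["R511G"] = [("antisense", 13, 3, 2)]    # 2 of 5 non-LOH confirmed
panels["F706S"] = [("antisense", 14, 2, 2)]    # 2 of 4 non-LOH confirmed

with open(out / "colonies.tsv", "w", newline="") as fh:
    w = csv.writer(fh, delimiter="\t", lineterminator="\n")
    w.writerow(["variant_id", "round", "colony_id", "allele_pcr", "sequence_call"])
    for vid, *_ in variants:
        for rnd, n_loh, n_bg, n_mut in panels[vid]:
            idx = 0
            for _ in range(n_loh):
                w.writerow([vid, rnd, f"{vid}.{rnd[0]}{idx:02d}", "wt_lost", "nt"]); idx += 1
            for _ in range(n_bg):
                w.writerow([vid, rnd, f"{vid}.{rnd[0]}{idx:02d}", "both", "wt"]); idx += 1
            for _ in range(n_mut):
                w.writerow([vid, rnd, f"{vid}.{rnd[0]}{idx:02d}", "both", "mut"]); idx += 1
print("rows:", sum(len(p) * 18 for p in panels.values()))
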