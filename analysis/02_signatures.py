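#!/usr/bin/env python
"""Length distributions and base-composition signatures per group.

Expected findings on the simulated cohort: three length modes at
22/30/33 nt in normal samples; ~70 % 5'U and elevated 10A in 24-30 nt
normal reads, near the random 25 % in tumors with CIS intermediate; a
5'G peak at 32-34 nt in every group.  Writes the per-sample length
histogram, per-group signature fractions and logo matrices under
results/signatures/.
"""

from pathlib import Path

from smallrna_atlas import io, signatures

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = SIM.parent / "signatures"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    design = io.read_table(SIM / "design.tsv")
    reads_by_sample = {s: io.read_reads(SIM / "reads" / f"{s}.tsv")
                       for s in design["sample_id"]}
    group_of = dict(zip(design["sample_id"], design["group"]))
    by_group: dict[str, list] = {}
    for s, df in reads_by_sample.items():
        by_group.setdefault(group_of[s], []).extend(df["seq"].tolist())

    hist = signatures.histogram_table(reads_by_sample)
    io.write_table(hist, OUT / "length_histogram.tsv")
    sig = signatures.signature_table(by_group)
    io.write_table(sig, OUT / "signature_fractions.tsv")
    io.write_table(signatures.logo_table(by_group), OUT / "logo_matrices.tsv")

    normal_hist = (hist[hist["sample"].str.startswith("normal")]
                   .groupby("length")["fraction"].mean())
    modes = normal_hist[normal_hist.diff() > 0].index
    print("normal-group length modes (local maxima):",
          [int(L) for L in (22, 30, 33)
           if normal_hist[L] > normal_hist[L - 1]
           and normal_hist[L] > normal_hist[L + 1]])
    for grp in ("normal", "CIS", "tumor"):
        t = sig[sig["group"] == grp].set_index("length")
        w = t.loc[24:30]
        frac = (w["frac_5U"] * w["n"]).sum() / w["n"].sum()
        frac10a = (w["frac_10A"] * w["n"]).sum() / w["n"].sum()
        g = t.loc[32:34]
        frac5g = (g["frac_5G"] * g["n"]).sum() / g["n"].sum()
        print(f"{grp:>7}: 5'U(24-30)={frac:.3f}  10A(24-30)={frac10a:.3f}  "
              f"5'G(32-34)={frac5g:.3f}")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
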