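"""Solvent-PRE effective net charge ϕ for wild type and the loop mutant at
pH 6.5 / 7.5, the pH differences Δϕ, and the cross-construct significance
filter (ΔΔϕ ≥ 0.4, all four σϕ ≤ 20% of |ϕ|).

Finding to look for: the mutant's planted low-pH gain of positive surface
charge near the active site makes those residues pass the filter, while the
pH-stable wild-type surface keeps everything else below threshold.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, TABLES, ensure_inputs  # noqa: E402

from premap.peaklist_io import read_peak_table  # noqa: E402
from premap.spre import build_phi_profile, delta_phi, significance_filter  # noqa: E402


def load_profile(tag: str):
    tables = {
        kind: read_peak_table(DATA / f"spre_{tag}_{kind}.tsv",
                              DATA / f"spre_{tag}_{kind}.tsv.meta.json")
        for kind in ("dia", "plus", "minus")
    }
    return build_phi_profile(tables["dia"], tables["plus"], tables["minus"])


def main() -> None:
    ensure_inputs()
    profiles = {tag: load_profile(tag) for tag in
                ("wt_65", "wt_75", "d215a_65", "d215a_75")}
    for tag, prof in profiles.items():
        prof.df.to_csv(TABLES / f"phi_{tag}.tsv", sep="\t", index=False)

    for construct, lo, hi in (("WT", "wt_65", "wt_75"),
                              ("D215A", "d215a_65", "d215a_75")):
        d = delta_phi(profiles[lo], profiles[hi])
        d.to_csv(TABLES / f"delta_phi_{construct.lower()}.tsv", sep="\t", index=False)
        used = d[~d["excluded"]]
        print(f"{construct}: mean |Δϕ(pH 6.5 − 7.5)| = "
              f"{used['delta_phi'].abs().mean():.2f} over {len(used)} residues")

    records, exclusions = significance_filter(
        profiles["wt_65"], profiles["wt_75"],
        profiles["d215a_65"], profiles["d215a_75"])
    records.to_csv(TABLES / "significance.tsv", sep="\t", index=False)
    exclusions.to_csv(TABLES / "significance_exclusions.tsv", sep="\t", index=False)
    sig = records[records["significant"]]
    print(f"significant divergence (ΔΔϕ ≥ 0.4, σ filter): "
          f"{sorted(sig['residue_index'])}")
    print(f"excluded residues: {len(exclusions)}")


if __name__ == "__main__":
    main()
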