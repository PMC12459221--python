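"""Generate all synthetic inputs for the analysis: PRE peak-table pairs for
the Trp- and Tyr-bound states (two-population loop ensemble, 8% excursion),
the 2×2 construct × pH solvent-PRE table triplets, and 600-frame dimer
snapshot sets with planted inter-protomer close-approach fractions (8% for
the Trp-like system, 0.5% for the Tyr-like one).

Writes tables, multi-model PDBs and truth files under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, SEED, ensure_inputs  # noqa: E402


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    ensure_inputs(seed)
    files = sorted(p.name for p in DATA.iterdir() if not p.name.startswith("."))
    print(f"seed {seed}: wrote {len(files)} files under {DATA}")
    for f in files:
        print(" ", f)


if __name__ == "__main__":
    main()
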