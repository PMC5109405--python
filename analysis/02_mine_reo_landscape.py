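"""Mine the stable REO landscape of the normal samples.

Pairs whose ordering holds in every one of the 34 pooled normal samples
form the landscape; the first platform's landscape is also compared with
the landscape of the remaining platforms, mirroring the two-set
concordance check that motivates pooling platforms at all.
"""

import json
from pathlib import Path

from reoresp import io
from reoresp.landscape import cross_set_concordance, find_stable_pairs

SIM = Path("results/analysis/simulated")
OUT = Path("results/analysis")


def main() -> None:
    normals = [
        io.read_expression(path, path.with_suffix("").with_suffix(".meta.tsv"))
        for path in sorted(SIM.glob("normals_platform_*.tsv"))
        if not path.name.endswith(".meta.tsv")
    ]
    stable = find_stable_pairs(normals, support_threshold=1.0)
    io.write_pairs(stable, OUT / "stable_pairs.tsv.gz")
    print(f"{stable.n_pairs} stable pairs over {len(stable.genes)} genes "
          f"({stable.n_supporting_samples} supporting samples)")

    set_a = find_stable_pairs(normals[:1])
    set_b = find_stable_pairs(normals[1:])
    conc = cross_set_concordance(set_a, set_b)
    with open(OUT / "landscape_concordance.json", "w") as fh:
        json.dump(conc.to_dict(), fh, indent=2)
    print(f"two-set concordance: {conc.s}/{conc.k} pairs agree "
          f"(score {conc.score:.3f}, log10 p = {conc.log10_p_value:.1f})")


if __name__ == "__main__":
    main()
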