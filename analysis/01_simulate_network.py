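#!/usr/bin/env python
"""Generate the synthetic flux-tower network used by the downstream analyses.

Emits a 48-site, 8-ecosystem-type daily dataset with a constructed 75%
positive-hysteresis site-year mix and 20% multiplicative flux noise, in the
same CSV dialect the reader consumes, plus the ground-truth parameter table.
"""

import argparse
from pathlib import Path

from ch4hyst.synthetic import gen_network, write_network


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-sites", type=int, default=48)
    ap.add_argument("--noise-cv", type=float, default=0.2)
    ap.add_argument("--positive-fraction", type=float, default=0.75)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic_network"))
    args = ap.parse_args()

    net = gen_network(
        n_sites=args.n_sites,
        seed=args.seed,
        positive_fraction=args.positive_fraction,
        flux_noise_cv=args.noise_cv,
    )
    write_network(net, args.out)
    n_sy = len(net.truth)
    print(f"wrote {args.n_sites} sites / {n_sy} site-years to {args.out}")
    print(f"constructed positive-hysteresis fraction: "
          f"{net.positive_fraction_constructed:.3f}")


if __name__ == "__main__":
    main()
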