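#!/usr/bin/env python
"""Full-scale MNIST benchmark runs (multi-hour; external data required).

Trains the multilayer-perceptron presets with and without adaptation, six
repeats each, and reports mean +/- SD test error.  Supply a directory
containing the four standard MNIST IDX files (never downloaded):

    python scripts/replicate_mnist.py --data-dir /path/to/mnist \
        --preset mlp-784-6-10 --out-dir runs/mnist
"""

import click

from eqadapt.cli import main as cli_main


@click.command()
@click.option("--data-dir", required=True, type=click.Path(exists=True))
@click.option("--preset", default="mlp-784-6-10", show_default=True,
              help="Base preset name; the -adp variant is run as well.")
@click.option("--out-dir", default="runs/mnist", show_default=True)
@click.option("--repeats", default=6, show_default=True)
@click.option("--seed", default=0, show_default=True)
def main(data_dir, preset, out_dir, repeats, seed):
    for name in (preset, preset + "-adp"):
        cli_main.main(
            [
                "train", "--preset", name, "--seed", str(seed),
                "--repeats", str(repeats),
                "--out-dir", f"{out_dir}/{name}",
                "--set", f"data.path={data_dir}",
            ],
            standalone_mode=False,
        )


if __name__ == "__main__":
    main()
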