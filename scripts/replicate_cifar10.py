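#!/usr/bin/env python
"""Full-scale CIFAR-10 convolutional EP runs (cluster-scale; external data).

Trains the convolutional presets with and without adaptation on the
standard pickled batches (never downloaded):

    python scripts/replicate_cifar10.py --data-dir /path/to/cifar-10-batches-py \
        --out-dir runs/cifar
"""

import click

from eqadapt.cli import main as cli_main


@click.command()
@click.option("--data-dir", required=True, type=click.Path(exists=True))
@click.option("--out-dir", default="runs/cifar", show_default=True)
@click.option("--repeats", default=6, show_default=True)
@click.option("--seed", default=0, show_default=True)
def main(data_dir, out_dir, repeats, seed):
    for name in ("cnn-cifar", "cnn-cifar-adp"):
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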