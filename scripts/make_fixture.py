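"""Regenerate the frozen regression fixture under tests/data/.

Writes the default synthetic bundle (seed 1) in the on-disk input formats,
then runs the full pipeline on the files as read back from disk and stores
the resulting artifacts as the expected outputs.  Run from the repository
root:

    python scripts/make_fixture.py
"""

from pathlib import Path

from adsim.pipeline import PipelineConfig, run_pipeline
from adsim.synthetic_data import BUNDLE_FILES, SyntheticConfig, generate_bundle, write_bundle

ROOT = Path(__file__).resolve().parent.parent
BUNDLE_DIR = ROOT / "tests" / "data" / "fixture_bundle"
EXPECTED_DIR = ROOT / "tests" / "data" / "fixture_expected"

FIXTURE_SEED = 1
FIXTURE_TOP_K = 10


def fixture_config(bundle_dir: Path = BUNDLE_DIR, output_dir: Path = EXPECTED_DIR) -> PipelineConfig:
    return PipelineConfig(
        ppi_path=str(bundle_dir / BUNDLE_FILES["ppi"]),
        functional_path=str(bundle_dir / BUNDLE_FILES["func"]),
        obo_path=str(bundle_dir / BUNDLE_FILES["obo"]),
        annotations_path=str(bundle_dir / BUNDLE_FILES["annotations"]),
        mapping_path=str(bundle_dir / BUNDLE_FILES["mapping"]),
        disease_genes_path=str(bundle_dir / BUNDLE_FILES["diseases"]),
        top_k=FIXTURE_TOP_K,
        output_dir=str(output_dir),
    )


def main() -> None:
    bundle = generate_bundle(SyntheticConfig(seed=FIXTURE_SEED))
    write_bundle(bundle, BUNDLE_DIR)
    run_pipeline(fixture_config())
    # metadata embeds absolute paths/checksums of this checkout; not part of
    # the frozen expectation
    (EXPECTED_DIR / "run_metadata.json").unlink(missing_ok=True)
    print(f"fixture bundle in {BUNDLE_DIR}")
    print(f"expected outputs in {EXPECTED_DIR}")


if __name__ == "__main__":
    main()
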