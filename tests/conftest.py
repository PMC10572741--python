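import pytest

from indigoferm import synthetic


@pytest.fixture(scope="session")
def big_dataset():
    """Fast-ORP-drop (big batch) synthetic dataset, fixed seed."""
    return synthetic.simulate_dataset(synthetic.SyntheticConfig.big_batch(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """Slow-ORP-drop (small batch) synthetic dataset, fixed seed."""
    return synthetic.simulate_dataset(synthetic.SyntheticConfig.small_batch(seed=7))


def write_gff3(path, records):
    """Write a toy GFF3 of CDS records.

    ``records`` are (contig, start, end, strand, gene, product) tuples;
    gene/product may be None.
    """
    lines = ["##gff-version 3"]
    for i, (contig, start, end, strand, gene, product) in enumerate(records):
        attrs = [f"ID=cds{i}"]
        if gene:
            attrs.append(f"gene={gene}")
        if product:
            attrs.append(f"product={product}")
        lines.append("\t".join(
            [contig, "test", "CDS", str(start), str(end), ".", strand, "0",
             ";".join(attrs)]))
    path.write_text("\n".join(lines) + "\n")
    return path
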