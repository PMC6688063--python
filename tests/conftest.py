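import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def write_vcf(tmp_path):
    """Write inline VCF text to a temp file.

    Meta lines (##...) are kept verbatim; column lines may be written with
    spaces and are re-joined with tabs.
    """

    def _write(text: str, name: str = "test.vcf"):
        path = tmp_path / name
        out = []
        for raw in text.strip().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                out.append(line)
            else:
                out.append("\t".join(line.split()))
        path.write_text("\n".join(out) + "\n")
        return str(path)

    return _write
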