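import pytest
from hypothesis import HealthCheck, settings

from helixcurate.star_io import ParticleRecord, ParticleSet

settings.register_profile(
    "ci",
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=50,
)
settings.load_profile("ci")


def make_record(**kwargs) -> ParticleRecord:
    defaults = dict(
        micrograph_id="mic_0001.mrc",
        tube_id=1,
        coord_x=100.0,
        coord_y=100.0,
        psi=0.0,
        tilt=90.0,
        rot=0.0,
        origin_x=0.0,
        origin_y=0.0,
        defocus_u=15000.0,
        defocus_v=14900.0,
        defocus_angle=0.0,
        pixel_size=1.045,
    )
    defaults.update(kwargs)
    return ParticleRecord(**defaults)


@pytest.fixture
def line_filament_records():
    """5 particles along +y, one subunit (26 px) apart."""
    return [
        make_record(coord_x=500.0, coord_y=500.0 + 26.0 * i, psi=0.0,
                    rot=(i * -166.7) % 360.0)
        for i in range(5)
    ]


@pytest.fixture
def star_text():
    def build(rows, columns=None, name="data_particles"):
        columns = columns or [
            "rlnMicrographName", "rlnHelicalTubeID",
            "rlnCoordinateX", "rlnCoordinateY", "rlnAnglePsi",
            "rlnDefocusU", "rlnDefocusV", "rlnImagePixelSize",
        ]
        lines = [name, "", "loop_"]
        lines += [f"_{c} #{i+1}" for i, c in enumerate(columns)]
        lines += [" ".join(str(v) for v in row) for row in rows]
        return "\n".join(lines) + "\n"
    return build


@pytest.fixture
def tiny_pdb(tmp_path):
    text = (
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504"
        "  1.00 10.00           N\n"
        "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147"
        "  1.00 12.00           C\n"
        "ATOM      3  CB  ALA A   1      12.919   6.841  -5.010"
        "  1.00 14.00           C\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path


def records_to_set(records) -> ParticleSet:
    return ParticleSet(list(records))
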