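import pytest

from tsi import BUNDLED_TABLE1, CellContext, load_binding_table

#: Assay volume implied by the bundled table's k_on/k_plus ratio (litres).
TABLE_VOLUME_L = 4.98e-10


@pytest.fixture(scope="session")
def table1():
    """The bundled T1 TCR binding table (6 rows, SP/DP x 4P/4A/4N)."""
    return load_binding_table(BUNDLED_TABLE1)


@pytest.fixture(scope="session")
def sp_rows(table1):
    return [p for p in table1 if p.cell_type == "SP thymocyte"]


@pytest.fixture(scope="session")
def dp_rows(table1):
    return [p for p in table1 if p.cell_type == "DP thymocyte"]


@pytest.fixture(scope="session")
def sp_4p(sp_rows):
    return next(p for p in sp_rows if p.ligand == "4P")


@pytest.fixture
def sp_context():
    """Single SP thymocyte at 10 nM ligand in the table-implied volume."""
    return CellContext(N_R=30000, N_c=1, volume=TABLE_VOLUME_L, rho=1e-8)
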