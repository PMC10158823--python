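import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from kivdesign import make_toy_network
from kivdesign.synthetic import ToyNetworkSpec


@pytest.fixture()
def toy_model():
    return make_toy_network()


@pytest.fixture()
def toy_model_u5():
    return make_toy_network(ToyNetworkSpec(glucose_uptake_cap=5.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# A minimal SBML L3 + FBC document: A -> B with bounds [0, 10], objective R1,
# GPR (g1 and g2) or g3. Used to check the FBC subset the reader supports.
SBML_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="mini" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
      <species id="B" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb0" value="0" constant="true"/>
      <parameter id="ub10" value="10" constant="true"/>
    </listOfParameters>
    <fbc:listOfGeneProducts>
      <fbc:geneProduct fbc:id="g1" fbc:label="g1"/>
      <fbc:geneProduct fbc:id="g2" fbc:label="g2"/>
      <fbc:geneProduct fbc:id="g3" fbc:label="g3"/>
    </fbc:listOfGeneProducts>
    <listOfReactions>
      <reaction id="{rxn1_id}" reversible="false" fast="false"
                fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub10">
        <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="B" stoichiometry="1" constant="true"/></listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:or>
            <fbc:and>
              <fbc:geneProductRef fbc:geneProduct="g1"/>
              <fbc:geneProductRef fbc:geneProduct="g2"/>
            </fbc:and>
            <fbc:geneProductRef fbc:geneProduct="g3"/>
          </fbc:or>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="{rxn2_id}" reversible="false" fast="false"
                fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub10">
        <listOfReactants><speciesReference species="B" stoichiometry="1" constant="true"/></listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="R1" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
"""


@pytest.fixture()
def mini_sbml(tmp_path):
    path = tmp_path / "mini.xml"
    path.write_text(SBML_TEMPLATE.format(rxn1_id="R1", rxn2_id="EX_B"))
    return path


@pytest.fixture()
def duplicate_id_sbml(tmp_path):
    path = tmp_path / "dup.xml"
    path.write_text(SBML_TEMPLATE.format(rxn1_id="R1", rxn2_id="R1"))
    return path
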