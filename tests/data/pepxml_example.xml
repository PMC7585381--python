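<?xml version="1.0" encoding="UTF-8"?>
<msms_pipeline_analysis>
  <msms_run_summary>
    <spectrum_query spectrum="example.0" start_scan="1" precursor_neutral_mass="998.485448" assumed_charge="2">
      <search_result>
        <search_hit hit_rank="1" peptide="PEPTIDEK" protein="sp|DEMO|DEMO">
          <search_score name="denovo_score" value="0.92"/>
          <search_score name="delta_score" value="0.10"/>
        </search_hit>
      </search_result>
    </spectrum_query>
    <spectrum_query spectrum="example.1" start_scan="2" precursor_neutral_mass="1278.645" assumed_charge="2">
      <search_result>
        <search_hit hit_rank="1" peptide="AMSTERDAM">
          <modification_info>
            <mod_aminoacid_mass position="2" mass="147.0354"/>
          </modification_info>
          <search_score name="denovo_score" value="0.66"/>
        </search_hit>
      </search_result>
    </spectrum_query>
  </msms_run_summary>
</msms_pipeline_analysis>
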