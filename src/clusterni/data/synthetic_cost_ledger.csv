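arm,strategy_code,school_id,amount
original,staff_session,shared,6888
original,champion_training,shared,11616
original,ongoing_support,shared,2064
original,equipment_pack,shared,2040
original,program_delivery,shared,2767
adapted,champion_training,shared,11616
adapted,ongoing_support,shared,2064
adapted,equipment_pack,shared,2040
adapted,program_delivery,shared,701
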