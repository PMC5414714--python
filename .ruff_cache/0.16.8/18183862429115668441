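/root/pkg/examples01_simulate_dataset.py02_pairwise_models_and_votes.py03_centroid_prediction.py04_leading_patterns.py  �   ����è�C�{������         �   ��������������                                         �   P�������g�����         �   ����g����j�����         B\�WbB\�Wb��������������������� �   ��������      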